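# A branch of the Habsburg royal family: the ancestry of Charles II of Spain.
# Printed names with spaces are encoded with underscores; individuals sharing
# a printed name are disambiguated by birth year.
Philip_I 0 0 1
Joanna 0 0 2
Isabella_of_Portugal 0 0 2
Anna_of_Bohemia 0 0 2
Christian_II 0 0 1
Albert_V 0 0 1
Francis_I_of_Lorraine 0 0 1
Charles_V Philip_I Joanna 1
Ferdinand_I Philip_I Joanna 1
Isabella_of_Austria Philip_I Joanna 2
Philip_II Charles_V Isabella_of_Portugal 1
Maria_of_Spain Charles_V Isabella_of_Portugal 2
Maximilian_II Ferdinand_I Anna_of_Bohemia 1
Anna_of_Austria_1528 Ferdinand_I Anna_of_Bohemia 2
Charles_II_of_Austria Ferdinand_I Anna_of_Bohemia 1
Christina_of_Denmark Christian_II Isabella_of_Austria 2
Anna_of_Austria_1549 Maximilian_II Maria_of_Spain 2
William_V Albert_V Anna_of_Austria_1528 1
Maria_Anna_of_Bavaria_1551 Albert_V Anna_of_Austria_1528 2
Renata Francis_I_of_Lorraine Christina_of_Denmark 2
Philip_III Philip_II Anna_of_Austria_1549 1
Margaret_of_Austria Charles_II_of_Austria Maria_Anna_of_Bavaria_1551 2
Ferdinand_II Charles_II_of_Austria Maria_Anna_of_Bavaria_1551 1
Maria_Anna_of_Bavaria_1574 William_V Renata 2
Philip_IV Philip_III Margaret_of_Austria 1
Maria_Anna_of_Spain Philip_III Margaret_of_Austria 2
Ferdinand_III Ferdinand_II Maria_Anna_of_Bavaria_1574 1
Mariana Ferdinand_III Maria_Anna_of_Spain 2
Charles_II Philip_IV Mariana 1
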