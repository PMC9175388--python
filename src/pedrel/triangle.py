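"""The relatedness (IBD) triangle.

A noninbred pairwise relationship with IBD coefficients
(kappa0, kappa1, kappa2) is a point (kappa0, kappa2) in the triangle
kappa0 >= 0, kappa2 >= 0, kappa0 + kappa2 <= 1.  Pedigree relationships can
never fall in Thompson's inadmissible region kappa1^2 < 4*kappa0*kappa2
(boundary inclusive, so e.g. half siblings at (1/2, 0) are admissible);
the region is shaded in rendered figures as a visual guide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fixtures import FIXTURE_PAIRS, builtin
from .identity import KappaTriple, kappa
from .pedigree import UndefinedKappa


@dataclass(frozen=True)
class TrianglePoint:
    k0: float
    k2: float
    label: str | None = None
    admissible: bool = True

    def __post_init__(self) -> None:
        if self.k0 < 0 or self.k2 < 0 or self.k0 + self.k2 > 1 + 1e-12:
            raise ValueError(
                f"({self.k0}, {self.k2}) is outside the triangle "
                "k0 >= 0, k2 >= 0, k0 + k2 <= 1")


def triangle_point(kap: KappaTriple, label: str | None = None) -> TrianglePoint:
    """Map an IBD triple to its triangle point with an admissibility flag."""
    if not kap.defined:
        raise UndefinedKappa(
            "kappa is undefined for this pair (at least one member is inbred); "
            "no triangle point exists")
    k0, k2 = float(kap.k0), float(kap.k2)
    k1 = 1.0 - k0 - k2
    return TrianglePoint(k0=k0, k2=k2, label=label,
                         admissible=k1 * k1 >= 4.0 * k0 * k2 - 1e-12)


def standard_points() -> list[TrianglePoint]:
    """The eight reference relationships of the triangle figure.

    Seven are computed from the built-in fixtures through the identity
    module; MZ (monozygotic twins) has no pedigree encoding and is the
    vertex (0, 1) by definition.
    """
    refs = [
        ("PO", "trio", ("1", "3")),
        ("UN", "trio", ("1", "2")),
        ("S", "full-siblings", None),
        ("H", "half-siblings", None),
        ("G", "grandparent", None),
        ("U", "aunt-nephew", None),
        ("FC", "first-cousins", None),
    ]
    out = []
    for label, fixture, pair in refs:
        ped = builtin(fixture)
        a, b = pair or FIXTURE_PAIRS[fixture]
        out.append(triangle_point(kappa(ped, a, b), label=label))
    out.append(TrianglePoint(k0=0.0, k2=1.0, label="MZ", admissible=True))
    return out


def render_triangle(points: list[TrianglePoint], out: str) -> dict:
    """Render the annotated triangle to ``out`` (and an .svg sibling when
    ``out`` ends in .png).  Returns a manifest describing what was drawn,
    so tests never have to compare pixels."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1, 0, 0], [0, 0, 1, 0], color="black", lw=1)

    # Thompson's inadmissible region: between the curve k0=(1-p)^2, k2=p^2
    # (where k1^2 = 4 k0 k2) and the hypotenuse k0 + k2 = 1.
    p = np.linspace(0.0, 1.0, 201)
    curve = np.column_stack([(1 - p) ** 2, p ** 2])
    hypo = np.column_stack([p, 1 - p])  # back along the hypotenuse
    region = np.vstack([curve, hypo])
    ax.fill(region[:, 0], region[:, 1], color="lightgrey", zorder=0,
            label="inadmissible")

    std = standard_points()
    for pt in std:
        ax.plot(pt.k0, pt.k2, "o", color="steelblue", ms=5)
        ax.annotate(pt.label, (pt.k0, pt.k2), textcoords="offset points",
                    xytext=(4, 4), fontsize=8)
    user = []
    for pt in points:
        marker = "X" if not pt.admissible else "D"
        ax.plot(pt.k0, pt.k2, marker, color="firebrick", ms=7)
        if pt.label:
            ax.annotate(pt.label, (pt.k0, pt.k2), textcoords="offset points",
                        xytext=(4, -10), fontsize=8, color="firebrick")
        user.append(pt)
        if not pt.admissible:
            import logging
            logging.getLogger(__name__).warning(
                "point (%s, %s) lies in the inadmissible region", pt.k0, pt.k2)
    ax.set_xlim(-0.02, 1.05)
    ax.set_ylim(-0.02, 1.05)
    ax.set_xlabel(r"$\kappa_0$")
    ax.set_ylabel(r"$\kappa_2$")
    fig.savefig(out, dpi=150)
    extra = None
    if out.endswith(".png"):
        extra = out[:-4] + ".svg"
        fig.savefig(extra)
    plt.close(fig)
    return {
        "file": out,
        "svg": extra,
        "standard_points": [(pt.label, pt.k0, pt.k2) for pt in std],
        "user_points": [(pt.label, pt.k0, pt.k2, pt.admissible) for pt in user],
        "region_vertices": len(region),
    }
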