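"""Collective variables and Gibbs free-energy landscapes.

A conformational ensemble is projected onto one or two scalar
collective variables (CVs) — here a center-of-mass distance and a
three-group interdomain angle — and the 2-D density histogram is
Boltzmann-inverted into a free-energy surface::

    G_ij = -kT ln(n_ij / n_max)

so the highest-density bin sits exactly at zero and empty bins are
masked rather than imputed.  Energies are stored in kT and convertible
to kJ/mol through the temperature (at 310 K, 1 kT = 2.577 kJ/mol).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Ensemble
from .selections import Selection, select
from . import geometry

BOLTZMANN_KJ_PER_MOL_K = 0.008314462618  # k_B in kJ/(mol K)


@dataclass(frozen=True)
class CVDefinition:
    """A named collective variable: a COM distance or a group angle.

    ``selections`` holds two expressions for a distance and three for an
    angle; ``vertex`` names the apex group of an angle ("a"/"b"/"c").
    """

    name: str
    kind: str  # "distance" | "angle"
    selections: tuple[str, ...]
    vertex: str = "b"
    weighting: str = "mass"

    @property
    def units(self) -> str:
        return "degrees" if self.kind == "angle" else "Å"


# Built-in reaction coordinates for the two-domain hinge protein
# (mature-sequence numbering): the Phe63 Cα to Asn-repeat (Asn113-Asn116)
# Cα-centroid distance, and the interdomain angle θ over three Cα groups
# with the second-listed group as the vertex.
BUILTIN_CVS: dict[str, CVDefinition] = {
    "phe63_asnrepeat_distance": CVDefinition(
        name="phe63_asnrepeat_distance",
        kind="distance",
        selections=("resid 63 and ca", "resid 113-116 and ca"),
    ),
    "interdomain_theta": CVDefinition(
        name="interdomain_theta",
        kind="angle",
        selections=(
            "resid 60-62,67-69 and ca",
            "resid 120-129 and ca",
            "resid 90-96,100-107 and ca",
        ),
        vertex="b",
    ),
}


@dataclass
class CVSeries:
    """Per-frame values of one collective variable."""

    name: str
    values: np.ndarray
    units: str
    definition: CVDefinition | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in CV series {self.name!r}")

    def __len__(self) -> int:
        return len(self.values)


def evaluate_cv(ensemble: Ensemble, definition: CVDefinition | str) -> CVSeries:
    """Evaluate a collective variable on every frame of an ensemble.

    ``definition`` may be a :class:`CVDefinition` or the name of a
    built-in one.  Raises if any selection resolves to zero atoms,
    naming the offending expression.
    """
    if isinstance(definition, str):
        try:
            definition = BUILTIN_CVS[definition]
        except KeyError:
            raise KeyError(
                f"unknown built-in CV {definition!r}; "
                f"available: {sorted(BUILTIN_CVS)}"
            ) from None
    sels: list[Selection] = []
    for expr in definition.selections:
        s = select(ensemble.topology, expr)
        if len(s) == 0:
            raise ValueError(
                f"CV {definition.name!r}: selection {expr!r} matches no atoms "
                "(missing residues in topology?)"
            )
        sels.append(s)
    if definition.kind == "distance":
        if len(sels) != 2:
            raise ValueError("distance CV needs exactly 2 selections")
        vals = geometry.group_distance(
            ensemble.coords, ensemble.topology, sels[0], sels[1],
            definition.weighting,
        )
    elif definition.kind == "angle":
        if len(sels) != 3:
            raise ValueError("angle CV needs exactly 3 selections")
        vals = geometry.group_angle(
            ensemble.coords, ensemble.topology, sels[0], sels[1], sels[2],
            definition.vertex, definition.weighting,
        )
    else:
        raise ValueError(f"unknown CV kind {definition.kind!r}")
    return CVSeries(
        name=definition.name,
        values=np.atleast_1d(vals),
        units=definition.units,
        definition=definition,
    )


@dataclass
class FreeEnergyLandscape:
    """2-D Gibbs free-energy surface over two collective variables.

    ``free_energy`` is in kT with the global minimum pinned at exactly
    zero; ``mask`` is True for empty bins (no samples, energy
    undefined).
    """

    bin_edges_x: np.ndarray
    bin_edges_y: np.ndarray
    counts: np.ndarray
    free_energy: np.ndarray
    mask: np.ndarray
    temperature: float
    cv_x_name: str = "cv_x"
    cv_y_name: str = "cv_y"
    units_x: str = ""
    units_y: str = ""

    @property
    def bin_centers_x(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_x[:-1] + self.bin_edges_x[1:])

    @property
    def bin_centers_y(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_y[:-1] + self.bin_edges_y[1:])

    @property
    def free_energy_kjmol(self) -> np.ndarray:
        """Energies converted from kT to kJ/mol at the stored temperature."""
        return self.free_energy * BOLTZMANN_KJ_PER_MOL_K * self.temperature

    def value_at(self, x: float, y: float) -> float:
        """Free energy (kT) of the bin containing (x, y)."""
        ix = int(np.clip(np.searchsorted(self.bin_edges_x, x, side="right") - 1,
                         0, len(self.bin_edges_x) - 2))
        iy = int(np.clip(np.searchsorted(self.bin_edges_y, y, side="right") - 1,
                         0, len(self.bin_edges_y) - 2))
        if self.mask[ix, iy]:
            return float("inf")
        return float(self.free_energy[ix, iy])


def build_fel(
    cv_x: CVSeries,
    cv_y: CVSeries,
    bins: int = 120,
    temperature: float = 310.0,
) -> FreeEnergyLandscape:
    """Boltzmann-invert the joint CV histogram into a free-energy surface.

    The grid spans the data range of each series with ``bins`` equal-
    width bins per axis (120 by default); the highest-density bin is
    set to zero.  Raises on a zero-variance axis (degenerate grid).
    """
    if len(cv_x) != len(cv_y):
        raise ValueError("CV series lengths differ")
    if len(cv_x) < 1:
        raise ValueError("need at least one sample")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = cv_x.values
    y = cv_y.values
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(
            "zero-variance CV series; the landscape grid is degenerate"
        )
    counts, ex, ey = np.histogram2d(x, y, bins=bins,
                                    range=[[x.min(), x.max()], [y.min(), y.max()]])
    counts = counts.astype(np.int64)
    mask = counts == 0
    g = np.full(counts.shape, np.nan)
    nmax = counts.max()
    with np.errstate(divide="ignore"):
        g[~mask] = -np.log(counts[~mask] / nmax) + 0.0  # +0.0 normalizes -0.0
    return FreeEnergyLandscape(
        bin_edges_x=ex, bin_edges_y=ey, counts=counts,
        free_energy=g, mask=mask, temperature=float(temperature),
        cv_x_name=cv_x.name, cv_y_name=cv_y.name,
        units_x=cv_x.units, units_y=cv_y.units,
    )


def locate_minima(
    fel: FreeEnergyLandscape,
    top_k: int | None = None,
    min_separation: int = 0,
) -> list[tuple[tuple[float, float], float]]:
    """Local minima of the landscape on the unmasked grid.

    A bin is a minimum when its energy is <= all unmasked 4-neighbours
    (masked neighbours do not disqualify).  Returned as
    ``((x_center, y_center), G)`` sorted ascending by G, ties broken by
    row-major bin index.

    ``min_separation`` suppresses duplicate minima of one basin: after
    the deepest minimum is taken, any further minimum within that many
    bins (Chebyshev distance) of an already-selected one is skipped —
    the usual way to read distinct basins off a sampled, noisy surface.
    """
    g = fel.free_energy
    mask = fel.mask
    nx, ny = g.shape
    found: list[tuple[float, int, int]] = []
    for i in range(nx):
        for j in range(ny):
            if mask[i, j]:
                continue
            gij = g[i, j]
            ok = True
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < nx and 0 <= nj < ny and not mask[ni, nj]:
                    if g[ni, nj] < gij:
                        ok = False
                        break
            if ok:
                found.append((gij, i, j))
    found.sort(key=lambda t: (t[0], t[1] * ny + t[2]))
    if min_separation > 0:
        kept: list[tuple[float, int, int]] = []
        for gval, i, j in found:
            if all(max(abs(i - ki), abs(j - kj)) > min_separation
                   for _, ki, kj in kept):
                kept.append((gval, i, j))
        found = kept
    cx, cy = fel.bin_centers_x, fel.bin_centers_y
    out = [((float(cx[i]), float(cy[j])), float(gval)) for gval, i, j in found]
    return out if top_k is None else out[:top_k]


def fel_to_tsv(fel: FreeEnergyLandscape) -> str:
    """Landscape as a TSV matrix with bin-center header rows; masked bins "NA"."""
    lines = [
        f"# free energy landscape, kT units, T={fel.temperature:g} K",
        f"# rows: {fel.cv_x_name} ({fel.units_x}); "
        f"columns: {fel.cv_y_name} ({fel.units_y})",
        "\t".join(["bin_center"] + [f"{c:.6g}" for c in fel.bin_centers_y]),
    ]
    for i, cx in enumerate(fel.bin_centers_x):
        row = [f"{cx:.6g}"]
        for j in range(len(fel.bin_centers_y)):
            row.append("NA" if fel.mask[i, j] else f"{fel.free_energy[i, j]:.6f}")
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
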