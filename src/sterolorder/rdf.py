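"""Lateral pair correlation functions and coordination-shell occupancies.

g(r) is computed per leaflet from the in-plane (x, y) minimum-image distance
between molecular centers of mass: the observed neighbor density in an
annulus around each reference, divided by the leaflet's mean target density
(excluding the reference itself for like-species pairs), averaged over frames
and leaflets.  For a homogeneous fluid g(r) -> 1.

Coordination shells default to 0.4-0.8 nm (first) and 0.8-1.1 nm (second);
the shell occupancy ratio is the annulus-area-weighted average of g over the
shell, which for sterol pairs quantifies how strongly direct sterol-sterol
contact is avoided in favor of the second shell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AnalysisError
from .io import Snapshot, min_image_shift, molecule_com
from .species import SpeciesMap

__all__ = [
    "RadialProfile",
    "ShellOccupancy",
    "DEFAULT_SHELLS",
    "min_image_lateral_distance",
    "lateral_rdf",
    "shell_density_ratio",
]

DEFAULT_SHELLS: tuple[tuple[float, float], ...] = ((0.4, 0.8), (0.8, 1.1))


@dataclass(frozen=True)
class RadialProfile:
    """Binned lateral pair correlation function."""

    edges: np.ndarray  # nm, uniform
    g: np.ndarray  # dimensionless, pooled over frames and leaflets
    counts: np.ndarray  # raw pair counts per bin (ints)
    sigma: np.ndarray  # Monte-Carlo standard error of g per bin
    mean_density: float  # mean target density, nm^-2
    n_frames: int
    species_pair: tuple[str, str]

    @property
    def r_mid(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"r_mid": self.r_mid, "g": self.g, "count": self.counts, "sem": self.sigma}
        )


@dataclass(frozen=True)
class ShellOccupancy:
    """Density ratio (relative to the mean) inside coordination shells."""

    shells: tuple[tuple[float, float], ...]  # nm
    ratios: tuple[float, ...]
    species_pair: tuple[str, str]


def min_image_lateral_distance(p, q, box) -> float:
    """Euclidean distance of the minimum-image in-plane displacement; z is
    ignored."""
    box = np.asarray(box, dtype=float)
    d = np.asarray(q, dtype=float)[:2] - np.asarray(p, dtype=float)[:2]
    d = min_image_shift(d, box[:2])
    return float(np.hypot(d[0], d[1]))


def _validate_shells(shells) -> tuple[tuple[float, float], ...]:
    shells = tuple((float(a), float(b)) for a, b in shells)
    prev = -np.inf
    for a, b in shells:
        if not b > a:
            raise AnalysisError(f"shell range ({a}, {b}) is not increasing")
        if a < prev:
            raise AnalysisError(f"shell ranges overlap at ({a}, {b})")
        prev = b
    return shells


def _pair_distances_setup(snapshots: Sequence[Snapshot], species_map: SpeciesMap,
                          species_a: str, species_b: str, com: str,
                          mode: str):
    """Yield (r_values, n_a, n_b_excl, area) per frame-leaflet unit."""
    if mode not in ("lateral", "3d"):
        raise AnalysisError(f"unknown distance mode {mode!r}")
    spec_a = species_map[species_a]
    spec_b = species_map[species_b]
    subset_a = com if spec_a.role == "sterol" else "whole"
    subset_b = com if spec_b.role == "sterol" else "whole"
    if com not in ("whole", "ring"):
        raise AnalysisError(f"unknown COM mode {com!r}")
    any_b = False
    for snap in snapshots:
        box = snap.box
        for leaflet in snap.leaflets:
            mols_a = snap.by_species(species_a, leaflet)
            mols_b = snap.by_species(species_b, leaflet)
            if not mols_a or not mols_b:
                if mols_b:
                    any_b = True
                continue
            any_b = True
            coms_a = np.array([molecule_com(m, spec_a, subset_a) for m in mols_a])
            if species_a == species_b and subset_a == subset_b:
                coms_b = coms_a
                ids_equal = True
            else:
                coms_b = np.array([molecule_com(m, spec_b, subset_b) for m in mols_b])
                ids_equal = False
            delta = coms_b[None, :, :] - coms_a[:, None, :]
            delta[..., :2] = min_image_shift(delta[..., :2], box[:2])
            if mode == "lateral":
                r = np.hypot(delta[..., 0], delta[..., 1])
            else:
                r = np.sqrt((delta**2).sum(axis=-1))
            if ids_equal:
                n = len(mols_a)
                r = r[~np.eye(n, dtype=bool)].ravel()
                n_b_excl = n - 1
            else:
                # distinct species never share a molecule id here
                r = r.ravel()
                n_b_excl = len(mols_b)
            yield r, len(mols_a), n_b_excl, snap.lateral_area
    if not any_b:
        raise AnalysisError(
            f"no {species_b!r} molecules found in any frame; cannot normalize g(r)"
        )


def lateral_rdf(snapshots: Sequence[Snapshot], species_map: SpeciesMap,
                species_a: str, species_b: str, *, bin_width: float = 0.01,
                r_max: float = 2.5, com: str = "whole", mode: str = "lateral"
                ) -> RadialProfile:
    """Lateral pair correlation function between two species.

    Pairs are restricted to one leaflet; ``com`` selects whole-molecule
    (default) or ring-only sterol centers; ``mode='3d'`` uses the full
    3D minimum-image distance instead of the in-plane one (for comparison).
    ``r_max`` beyond half the smallest lateral box length is truncated with a
    warning.
    """
    if not snapshots:
        raise AnalysisError("lateral_rdf needs at least one snapshot")
    if bin_width <= 0:
        raise AnalysisError("bin width must be > 0")
    half_min_box = min(float(min(s.box[0], s.box[1])) for s in snapshots) / 2.0
    if r_max > half_min_box:
        warnings.warn(
            f"r_max={r_max} exceeds half the smallest lateral box length "
            f"({half_min_box:.3f} nm); truncating",
            stacklevel=2,
        )
        r_max = half_min_box
    n_bins = int(np.floor(r_max / bin_width + 1e-12))
    edges = np.arange(n_bins + 1) * bin_width
    annulus = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)

    counts = np.zeros(n_bins, dtype=np.int64)
    norm = np.zeros(n_bins)
    density_sum = 0.0
    n_units = 0
    frames = set()
    for snap in snapshots:
        frames.add(snap.frame_index)
    for r, n_a, n_b_excl, area in _pair_distances_setup(
        snapshots, species_map, species_a, species_b, com, mode
    ):
        c, _ = np.histogram(r, bins=edges)
        counts += c
        rho = n_b_excl / area
        norm += n_a * rho * annulus
        density_sum += rho
        n_units += 1
    if n_units == 0:
        raise AnalysisError(
            f"no ({species_a}, {species_b}) pairs share a leaflet in any frame"
        )
    # Unordered pair counts of a homogeneous process are Poisson; for a
    # like-species pair each unordered pair is counted twice (i->j and j->i),
    # which doubles the variance of the binned count.
    var_factor = 2.0 if species_a == species_b else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(norm > 0, counts / norm, 0.0)
        sigma = np.where(
            norm > 0, np.sqrt(var_factor * np.maximum(norm, 1e-300)) / norm, np.inf
        )
    return RadialProfile(
        edges=edges,
        g=g,
        counts=counts,
        sigma=sigma,
        mean_density=density_sum / n_units,
        n_frames=len(frames),
        species_pair=(species_a, species_b),
    )


def shell_density_ratio(snapshots: Sequence[Snapshot], species_map: SpeciesMap,
                        species_a: str, species_b: str,
                        shells: Sequence[tuple[float, float]] = DEFAULT_SHELLS,
                        *, com: str = "whole", mode: str = "lateral"
                        ) -> ShellOccupancy:
    """Target density inside each shell annulus relative to the mean density.

    Equals the annulus-area-weighted average of g(r) over the shell range
    (exactly so when bin edges align with shell boundaries).
    """
    shells = _validate_shells(shells)
    if not snapshots:
        raise AnalysisError("shell_density_ratio needs at least one snapshot")
    counts = np.zeros(len(shells))
    norm = np.zeros(len(shells))
    for r, n_a, n_b_excl, area in _pair_distances_setup(
        snapshots, species_map, species_a, species_b, com, mode
    ):
        rho = n_b_excl / area
        for k, (lo, hi) in enumerate(shells):
            counts[k] += int(((r >= lo) & (r < hi)).sum())
            norm[k] += n_a * rho * np.pi * (hi**2 - lo**2)
    if not norm.any():
        raise AnalysisError(
            f"no ({species_a}, {species_b}) pairs share a leaflet in any frame"
        )
    ratios = tuple(float(c / n) if n > 0 else 0.0 for c, n in zip(counts, norm))
    return ShellOccupancy(shells=shells, ratios=ratios, species_pair=(species_a, species_b))
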