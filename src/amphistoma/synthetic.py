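"""Synthetic leaf-surface generators.

Four pattern families cover the study conditions:

* ``random_surface`` — complete spatial randomness (the null model);
* ``triangular_grid_surface`` — the ideal pattern: an equilateral triangular
  lattice, conditioned on holding exactly ``n`` stomata in the window after
  integrating over density uncertainty (count ~ Poisson(λ), λ ~ Γ(n, 1),
  the posterior of the rate under a flat prior);
* ``hardcore_surface`` — an inhibition (minimum-distance) process standing
  in for observed overdispersed-but-not-ideal patterning;
* ``simulate_pair`` — paired abaxial/adaxial surfaces that are independent,
  perfectly aligned, or offset-coordinated (adaxial lattice shifted by half
  a lattice vector, the idealized amphistomatous arrangement).

``attach_lengths`` plants a known affine association between guard-cell
length and Voronoi zone area so that downstream slope estimation can be
checked by parameter recovery.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .leaf_data import DEFAULT_WINDOW_SIDE, PairedSurfaces, SurfaceRecord

logger = logging.getLogger(__name__)

_SQRT3 = math.sqrt(3.0)
DEFAULT_WINDOW = (DEFAULT_WINDOW_SIDE, DEFAULT_WINDOW_SIDE)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GridSimConfig:
    """Settings for the conditioned triangular-lattice simulation."""

    n_target: int
    window: tuple[float, float] = DEFAULT_WINDOW
    max_rejections: int = 10_000
    randomize_rotation: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_target < 1:
            raise ValueError("n_target must be >= 1")
        if self.max_rejections < 1:
            raise ValueError("max_rejections must be >= 1")


@dataclass(frozen=True)
class PairSimConfig:
    """Settings for paired abaxial/adaxial simulation."""

    n_ab: int
    n_ad: int
    window: tuple[float, float] = DEFAULT_WINDOW
    mode: str = "independent"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_ab < 0 or self.n_ad < 0:
            raise ValueError("counts must be >= 0")
        if self.mode not in ("independent", "aligned", "offset_coordinated"):
            raise ValueError(f"unknown mode {self.mode!r}")


def random_surface(n: int, window=DEFAULT_WINDOW, seed=None, *,
                   surface_id: str = "random", surface: str = "abaxial") -> SurfaceRecord:
    """``n`` stomata i.i.d. uniform over the window (complete spatial randomness)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _rng(seed)
    xy = rng.uniform((0.0, 0.0), window, size=(n, 2)) if n else np.empty((0, 2))
    return SurfaceRecord(surface_id=surface_id, surface=surface, window=tuple(window), xy=xy)


def random_points_batch(n: int, window, rng: np.random.Generator, size: int) -> np.ndarray:
    """``size`` independent uniform point sets, shape (size, n, 2)."""
    return rng.uniform((0.0, 0.0), window, size=(size, n, 2))


def ideal_grid_spacing(density: float) -> float:
    """Equilateral-lattice spacing U (μm) for an areal density (mm⁻²).

    A triangular lattice with nearest-neighbour distance U has density
    2 / (√3 U²), so U = √(2 / (√3 ρ)).
    """
    if density <= 0:
        raise ValueError("density must be positive")
    return math.sqrt(2.0 / (_SQRT3 * density)) * 1000.0


def ideal_grid_density(spacing_um: float) -> float:
    """Inverse of :func:`ideal_grid_spacing`: density (mm⁻²) for spacing U (μm)."""
    if spacing_um <= 0:
        raise ValueError("spacing must be positive")
    u_mm = spacing_um / 1000.0
    return 2.0 / (_SQRT3 * u_mm * u_mm)


def _lattice_index_grid(a_min: float, window, margin: float = 2.0):
    """Index ranges (i, j) generous enough to cover the window for any
    translation/rotation at lattice constant >= a_min."""
    w, h = window
    radius = 0.5 * math.hypot(w, h) + margin * a_min
    ni = int(math.ceil(radius / a_min)) + 2
    nj = int(math.ceil(radius / (a_min * _SQRT3 / 2.0))) + 2
    i = np.arange(-ni, ni + 1)
    j = np.arange(-nj, nj + 1)
    ii, jj = np.meshgrid(i, j, indexing="xy")
    return ii.ravel().astype(float), jj.ravel().astype(float)


def _lattice_cloud(a, theta, t1, t2, window, ii, jj):
    """Lattice points (centered on the window) for per-attempt parameter
    arrays; returns (x, y) each of shape (B, M) in window coordinates."""
    a = np.asarray(a, float)[:, None]
    t1 = np.asarray(t1, float)[:, None]
    t2 = np.asarray(t2, float)[:, None]
    theta = np.asarray(theta, float)[:, None]
    # basis v1 = (a, 0), v2 = (a/2, a*sqrt(3)/2); fractional translation (t1, t2)
    lx = ((ii[None, :] + t1) + 0.5 * (jj[None, :] + t2)) * a
    ly = (jj[None, :] + t2) * (a * _SQRT3 / 2.0)
    c, s = np.cos(theta), np.sin(theta)
    x = c * lx - s * ly + window[0] / 2.0
    y = s * lx + c * ly + window[1] / 2.0
    return x, y


def conditioned_lattice_sample(
    n_target: int,
    window=DEFAULT_WINDOW,
    size: int = 1,
    seed=None,
    *,
    max_rejections: int = 10_000,
    randomize_rotation: bool = True,
    return_params: bool = False,
):
    """Draw ``size`` conditioned ideal-lattice point sets, shape (size, n, 2).

    Each draw integrates over density uncertainty — λ ~ Γ(n_target, 1),
    count ~ Poisson(λ) — builds an equilateral triangular lattice of density
    count/area with a uniformly random translation (and rotation over
    [0°, 60°) when enabled), and accepts only windows holding exactly
    ``n_target`` points.  Rejection never alters the lattice geometry, only
    which density/translation/rotation draws survive.

    Rotation randomization defaults on: a translation-only lattice admits
    only a quantized set of in-window counts (rows x columns), so for many
    ``n_target`` the exact-count event has essentially zero probability and
    conditioning is infeasible without rotation.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    rng = _rng(seed)
    w, h = window
    area = w * h
    budget = max_rejections * size
    attempts = 0
    n_accepted = 0
    accepted: list[np.ndarray] = []
    params: list[tuple[float, float, float, float]] = []

    # plausible smallest spacing (largest count) for sizing the index grid
    count_hi = n_target + 10.0 * math.sqrt(2.0 * n_target) + 10.0
    a_min = math.sqrt(2.0 * area / (_SQRT3 * count_hi))
    ii, jj = _lattice_index_grid(a_min, window)
    m = ii.size
    batch = max(64, min(4096, 4_000_000 // max(m, 1)))

    while n_accepted < size and attempts < budget:
        b = min(batch, budget - attempts)
        attempts += b
        lam = rng.gamma(n_target, 1.0, b)
        counts = rng.poisson(lam).astype(float)
        counts = np.maximum(counts, 1.0)
        counts = np.minimum(counts, count_hi)  # grid sized for this bound
        a = np.sqrt(2.0 * area / (_SQRT3 * counts))
        theta = (rng.uniform(0.0, math.pi / 3.0, b) if randomize_rotation
                 else np.zeros(b))
        t1 = rng.uniform(0.0, 1.0, b)
        t2 = rng.uniform(0.0, 1.0, b)
        x, y = _lattice_cloud(a, theta, t1, t2, window, ii, jj)
        inside = (x >= 0.0) & (x <= w) & (y >= 0.0) & (y <= h)
        n_in = inside.sum(axis=1)
        hits = np.nonzero(n_in == n_target)[0][: size - n_accepted]
        if hits.size:
            sub = inside[hits]
            xs = x[hits][sub].reshape(hits.size, n_target)
            ys = y[hits][sub].reshape(hits.size, n_target)
            accepted.append(np.stack([xs, ys], axis=-1))
            params.extend(
                (float(a[k]), float(theta[k]), float(t1[k]), float(t2[k]))
                for k in hits
            )
            n_accepted += hits.size

    if n_accepted < size:
        rate = n_accepted / attempts if attempts else 0.0
        raise RuntimeError(
            f"conditioned-lattice rejection budget exhausted: {n_accepted}/{size} "
            f"accepted in {attempts} attempts (acceptance rate {rate:.4f}); "
            "raise max_rejections"
        )
    logger.debug("conditioned lattice: %d/%d accepted (rate %.3f)",
                 size, attempts, size / attempts)
    points = np.concatenate(accepted, axis=0)
    if return_params:
        return points, params
    return points


def triangular_grid_surface(config: GridSimConfig) -> SurfaceRecord:
    """One conditioned ideal-lattice surface with exactly ``n_target`` stomata."""
    pts = conditioned_lattice_sample(
        config.n_target, config.window, size=1, seed=config.seed,
        max_rejections=config.max_rejections,
        randomize_rotation=config.randomize_rotation,
    )[0]
    return SurfaceRecord(surface_id="ideal_grid", window=tuple(config.window), xy=pts)


def hardcore_surface(n: int, window=DEFAULT_WINDOW, r_min: float = 0.0, seed=None, *,
                     max_attempts: int | None = None,
                     surface_id: str = "hardcore", surface: str = "abaxial") -> SurfaceRecord:
    """``n`` points by sequential dart throwing with pairwise distance >= r_min."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _rng(seed)
    if max_attempts is None:
        max_attempts = 10_000 * max(n, 1)
    pts = np.empty((n, 2))
    placed = 0
    attempts = 0
    r2 = r_min * r_min
    while placed < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"hard-core packing infeasible: placed {placed}/{n} points with "
                f"r_min={r_min} in {attempts} attempts"
            )
        attempts += 1
        p = rng.uniform((0.0, 0.0), window)
        if placed and r2 > 0:
            d2 = np.sum((pts[:placed] - p) ** 2, axis=1)
            if d2.min() < r2:
                continue
        pts[placed] = p
        placed += 1
    return SurfaceRecord(surface_id=surface_id, surface=surface,
                         window=tuple(window), xy=pts[:n])


def simulate_pair(config: PairSimConfig) -> PairedSurfaces:
    """Simulate one abaxial/adaxial pair under the configured coupling.

    ``independent`` draws both surfaces from complete spatial randomness;
    ``aligned`` places the adaxial stomata exactly over the abaxial ones;
    ``offset_coordinated`` builds a conditioned triangular lattice on the
    abaxial side and translates it by half the (a, 0) basis vector for the
    adaxial side (the idealized coordinated arrangement), clipping to the
    window — in that mode the adaxial count is whatever falls inside and
    ``n_ad`` is ignored.
    """
    rng = _rng(config.seed)
    w, h = config.window
    if config.mode == "independent":
        ab = random_surface(config.n_ab, config.window, rng,
                            surface_id="pair:ab", surface="abaxial")
        ad = random_surface(config.n_ad, config.window, rng,
                            surface_id="pair:ad", surface="adaxial")
    elif config.mode == "aligned":
        ab = random_surface(config.n_ab, config.window, rng,
                            surface_id="pair:ab", surface="abaxial")
        ad = SurfaceRecord(surface_id="pair:ad", surface="adaxial",
                           window=tuple(config.window), xy=ab.xy.copy())
    else:  # offset_coordinated
        pts, params = conditioned_lattice_sample(
            config.n_ab, config.window, size=1, seed=rng, return_params=True)
        a, theta, t1, t2 = params[0]
        ab = SurfaceRecord(surface_id="pair:ab", surface="abaxial",
                           window=tuple(config.window), xy=pts[0])
        ii, jj = _lattice_index_grid(a, config.window)
        # the same lattice shifted by half a basis vector: t1 -> t1 + 1/2
        x, y = _lattice_cloud([a], [theta], [t1 + 0.5], [t2], config.window, ii, jj)
        inside = (x[0] >= 0) & (x[0] <= w) & (y[0] >= 0) & (y[0] <= h)
        ad_xy = np.column_stack([x[0][inside], y[0][inside]])
        if ad_xy.shape[0] != config.n_ad:
            logger.debug("offset_coordinated pair: adaxial count %d (n_ad ignored)",
                         ad_xy.shape[0])
        ad = SurfaceRecord(surface_id="pair:ad", surface="adaxial",
                           window=tuple(config.window), xy=ad_xy)
    return PairedSurfaces(leaf_id="pair", abaxial=ab, adaxial=ad)


def attach_lengths(record: SurfaceRecord, alpha: float, beta: float,
                   sigma: float, seed=None) -> SurfaceRecord:
    """Plant guard-cell lengths affine in Voronoi zone area.

    length_i = alpha + beta * zone_area_i + N(0, sigma), clipped positive;
    alpha and sigma in μm, beta in μm per mm² of zone area.
    """
    if record.n < 1:
        raise ValueError("record must contain at least one stomate")
    from .zones import voronoi_zones

    rng = _rng(seed)
    areas = voronoi_zones(record).areas
    noise = rng.normal(0.0, sigma, record.n) if sigma > 0 else 0.0
    lengths = np.maximum(alpha + beta * areas + noise, 1e-6)
    return record.with_lengths(lengths)


# densities (mm^-2) emulating the observed regime: abaxial surfaces carry
# more stomata, high light raises density; adaxial = 0.8 x abaxial gives an
# amphistomy ratio ad/(ab+ad) ~ 0.44
STUDY_DENSITIES = {"low": 150.0, "medium": 200.0, "high": 400.0}
ADAXIAL_FRACTION = 0.8

# planted length-zone association: ~20 um guard cells whose length rises
# with local supply-zone area, plus measurement-scale noise
STUDY_LENGTH_PARAMS = {"alpha": 18.0, "beta": 600.0, "sigma": 2.0}


def synthetic_study(n_pairs: int = 66, window=DEFAULT_WINDOW, seed=None,
                    treatments=("low", "medium", "high"),
                    leaves_per_plant: int = 2):
    """A complete synthetic study mirroring the design scale of the data set
    this package emulates: ``n_pairs`` leaves split across light treatments,
    two leaves per plant, hard-core (overdispersed) patterning, and planted
    guard-cell lengths.  Returns a flat list of SurfaceRecords.
    """
    rng = _rng(seed)
    records: list[SurfaceRecord] = []
    area = window[0] * window[1]
    per_treatment = [n_pairs // len(treatments)] * len(treatments)
    for i in range(n_pairs - sum(per_treatment)):
        per_treatment[i] += 1
    leaf_counter = 0
    for treatment, n_leaves in zip(treatments, per_treatment):
        dens_ab = STUDY_DENSITIES.get(treatment, 200.0)
        for k in range(n_leaves):
            plant = f"{treatment}_p{k // leaves_per_plant:02d}"
            leaf = f"leaf{leaf_counter:03d}"
            leaf_counter += 1
            for surface, dens in (("abaxial", dens_ab),
                                  ("adaxial", dens_ab * ADAXIAL_FRACTION)):
                n = max(int(rng.poisson(dens * area)), 3)
                r_min = 0.4 / math.sqrt(dens)
                rec = hardcore_surface(
                    n, window, r_min, rng,
                    surface_id=f"{plant}:{leaf}:{surface}", surface=surface)
                rec = attach_lengths(rec, seed=rng, **STUDY_LENGTH_PARAMS)
                records.append(
                    SurfaceRecord(
                        surface_id=rec.surface_id, plant_id=plant, leaf_id=leaf,
                        surface=surface, treatment=treatment, window=tuple(window),
                        xy=rec.xy, lengths=rec.lengths,
                    )
                )
    return records
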