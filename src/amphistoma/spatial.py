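"""Nearest-neighbour dispersion statistics and Monte-Carlo tests.

The nearest-neighbour index (NNI) is the ratio of the observed mean
nearest-neighbour distance D̄_O to the expectation under complete spatial
randomness, D̄_E = 0.5·√(A/n).  NNI ≈ 1 for random patterns, rises with
overdispersion, and reaches ≈ 2.149 for an equilateral triangular lattice.
The dispersion index (DI) rescales NNI so that the median of a random
Monte-Carlo null sits at 0 and the median of the conditioned ideal-lattice
simulation sits at 1.  No edge correction is applied to D̄_O: boundary bias
cancels because the synthetic nulls share the window geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .leaf_data import DispersionResult, SurfaceRecord
from .synthetic import conditioned_lattice_sample, random_points_batch, _rng


@dataclass(frozen=True)
class NNIResult:
    """Observed and expected mean nearest-neighbour distance and their ratio."""

    d_obs_mean: float
    d_exp_mean: float
    nni: float


def expected_nn_distance(area: float, n: int) -> float:
    """Expected mean nearest-neighbour distance under randomness: 0.5·√(A/n)."""
    if area <= 0:
        raise ValueError("area must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    return 0.5 * math.sqrt(area / n)


def observed_mean_nn_distance(record: SurfaceRecord) -> float:
    """Mean distance from each stomate to its nearest neighbour (no edge
    correction)."""
    if record.n < 2:
        raise ValueError("need at least 2 stomata for nearest-neighbour distances")
    tree = cKDTree(record.xy)
    d, _ = tree.query(record.xy, k=2)
    return float(d[:, 1].mean())


def nni(record: SurfaceRecord) -> NNIResult:
    """Nearest-neighbour index D̄_O / D̄_E for one surface."""
    d_obs = observed_mean_nn_distance(record)
    d_exp = expected_nn_distance(record.window_area, record.n)
    return NNIResult(d_obs_mean=d_obs, d_exp_mean=d_exp, nni=d_obs / d_exp)


def mean_nn_batch(points: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Mean nearest-neighbour distance for each point set in a (m, n, 2)
    stack, by chunked pairwise distances."""
    m, n, _ = points.shape
    if n < 2:
        raise ValueError("need at least 2 points per set")
    out = np.empty(m)
    for lo in range(0, m, chunk):
        p = points[lo:lo + chunk]
        diff = p[:, :, None, :] - p[:, None, :, :]
        d2 = np.einsum("mijk,mijk->mij", diff, diff)
        idx = np.arange(n)
        d2[:, idx, idx] = np.inf
        out[lo:lo + chunk] = np.sqrt(d2.min(axis=2)).mean(axis=1)
    return out


def dispersion_index(nni_obs: float, nni_random: Sequence[float],
                     nni_ideal: Sequence[float]) -> float:
    """DI = (NNI − median(random)) / (median(ideal) − median(random)).

    0 means the pattern matches the random-null median, 1 the ideal-lattice
    median; observed surfaces may fall outside [0, 1].
    """
    nni_random = np.asarray(nni_random, float)
    nni_ideal = np.asarray(nni_ideal, float)
    if nni_random.size == 0 or nni_ideal.size == 0:
        raise ValueError("null samples must be non-empty")
    med_r = float(np.median(nni_random))
    med_i = float(np.median(nni_ideal))
    denom = med_i - med_r
    if denom == 0:
        raise ValueError("degenerate dispersion index: identical null medians")
    return (nni_obs - med_r) / denom


def mc_p_greater(observed: float, synthetic: Sequence[float]) -> float:
    """Add-one Monte-Carlo p-value for the one-tailed alternative that the
    observed statistic exceeds the synthetic distribution; ties count
    against rejection and p is never exactly 0."""
    synthetic = np.asarray(synthetic, float)
    if synthetic.size == 0:
        raise ValueError("synthetic sample must be non-empty")
    return (1 + int(np.sum(synthetic >= observed))) / (1 + synthetic.size)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-aligned with the
    input, monotone and capped at 1."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def dispersion_analysis(record: SurfaceRecord, n_sim: int = 1000,
                        seed=None) -> DispersionResult:
    """Full single-surface dispersion analysis.

    Simulates ``n_sim`` random-uniform surfaces and ``n_sim`` conditioned
    triangular-lattice surfaces matched to the record's window and count,
    then reports the observed NNI, the two null medians, DI, and the raw
    one-tailed overdispersion p-value.  One simulation set serves both the
    p-value and DI.  Family-wise adjustment happens at batch level
    (:func:`dispersion_batch`).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = _rng(seed)
    obs = nni(record)
    d_exp = obs.d_exp_mean
    rand_pts = random_points_batch(record.n, record.window, rng, n_sim)
    nni_random = mean_nn_batch(rand_pts) / d_exp
    ideal_pts = conditioned_lattice_sample(record.n, record.window, n_sim, rng)
    nni_ideal = mean_nn_batch(ideal_pts) / d_exp
    return DispersionResult(
        surface_id=record.surface_id,
        nni_observed=obs.nni,
        nni_random_median=float(np.median(nni_random)),
        nni_ideal_median=float(np.median(nni_ideal)),
        dispersion_index=dispersion_index(obs.nni, nni_random, nni_ideal),
        p_raw=mc_p_greater(obs.nni, nni_random),
        n_sim=n_sim,
    )


def dispersion_batch(records: Sequence[SurfaceRecord], n_sim: int = 1000,
                     seed=None) -> pd.DataFrame:
    """Dispersion analysis over a family of surfaces with BH adjustment
    across the whole family (every single-surface test forms one family)."""
    rng = _rng(seed)
    results = [dispersion_analysis(rec, n_sim=n_sim, seed=rng) for rec in records]
    adj = bh_adjust([r.p_raw for r in results]) if results else []
    rows = []
    for r, p_adj in zip(results, adj):
        rows.append({
            "surface_id": r.surface_id,
            "nni_observed": r.nni_observed,
            "nni_random_median": r.nni_random_median,
            "nni_ideal_median": r.nni_ideal_median,
            "dispersion_index": r.dispersion_index,
            "p_raw": r.p_raw,
            "p_adjusted": float(p_adj),
            "n_sim": r.n_sim,
        })
    return pd.DataFrame(rows)


def two_way_anova(values: Sequence[float], factor_a: Sequence,
                  factor_b: Sequence) -> pd.DataFrame:
    """Two-factor ANOVA with interaction, Type-II sums of squares.

    Returns a table indexed by effect (``A``, ``B``, ``A:B``, ``Residual``)
    with sum-of-squares, df, F and p columns.  Type II keeps main-effect
    tests well defined for unbalanced layouts.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "value": np.asarray(values, float),
        "A": pd.Categorical(factor_a),
        "B": pd.Categorical(factor_b),
    })
    if df["value"].size - df["A"].nunique() * df["B"].nunique() < 1:
        raise ValueError("no residual degrees of freedom")
    model = smf.ols("value ~ C(A) * C(B)", data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient design: some factor cells are empty")
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(index={"C(A)": "A", "C(B)": "B", "C(A):C(B)": "A:B"})
    table = table.rename(columns={"sum_sq": "sum_sq", "df": "df", "F": "F", "PR(>F)": "p"})
    return table
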