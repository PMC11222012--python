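"""State-contrast statistics: band-wise ANOVA with Bonferroni correction and
top-k connectivity-difference maps.

The contrast of interest is the one-way ANOVA of a connectivity or topology
feature across the three driving states, computed per (estimator, band) and
Bonferroni-adjusted over the declared family of tests (default: the number
of estimator x band cells in the run).  ``power_check`` calibrates the
whole stage on the synthetic generator: it simulates small cohorts and
reports the fraction of simulations in which the corrected contrast is
significant, yielding a type-I rate under a null cohort and power under an
effect cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from distractnet.bands import BAND_ORDER, CANONICAL_BANDS
from distractnet.connectivity import mean_strength, plv_matrix, coh_matrix, sl_matrix
from distractnet.connectivity import SpectralParams, SLParams
from distractnet.preprocessing import STATES, decompose_bands
from distractnet.synthetic import CohortSpec, generate_cohort
from distractnet.topology import _ranked_pairs

ALPHA_DEFAULT = 0.05


@dataclass
class StateContrastResult:
    """One-way ANOVA of a feature across states, with Bonferroni adjustment."""

    feature: str
    band: str
    group_means: dict[str, float]
    f_stat: float
    p_raw: float
    p_adjusted: float
    n_tests: int

    def __post_init__(self) -> None:
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")

    @property
    def significant(self) -> bool:
        return self.p_adjusted < ALPHA_DEFAULT


def anova_states(
    groups: Mapping[str, Sequence[float]],
    n_tests: int = 1,
    feature: str = "",
    band: str = "",
) -> StateContrastResult:
    """One-way ANOVA across state groups; adjusted p = min(1, n_tests * p).

    Degenerate input with zero variance everywhere and equal means takes
    the F = 0, p = 1 path.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {k!r} needs at least 2 values, got {a.size}")
    vals = list(arrays.values())
    if all(a.std() == 0 for a in vals) and len({a.mean() for a in vals}) == 1:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = sps.f_oneway(*vals)
        if not np.isfinite(p):
            f_stat, p = 0.0, 1.0
    return StateContrastResult(
        feature=feature,
        band=band,
        group_means={k: float(a.mean()) for k, a in arrays.items()},
        f_stat=float(f_stat),
        p_raw=float(p),
        p_adjusted=float(min(1.0, n_tests * p)),
        n_tests=n_tests,
    )


def contrast_table(
    feature_table: pd.DataFrame,
    columns: Sequence[str] | None = None,
    n_tests: int | None = None,
    by_subject: bool = False,
) -> pd.DataFrame:
    """ANOVA of each feature column across states, Bonferroni-corrected.

    The family size defaults to the number of tested columns.  With
    ``by_subject=True`` the unit of analysis is the subject mean rather
    than the epoch.
    """
    cols = list(
        columns
        if columns is not None
        else [c for c in feature_table.columns if c not in ("state", "subject", "epoch")]
    )
    m = n_tests if n_tests is not None else len(cols)
    data = feature_table
    if by_subject:
        data = (
            feature_table.groupby(["state", "subject"], as_index=False)[cols].mean()
        )
    rows = []
    for col in cols:
        parts = col.split("_")
        band = parts[1] if len(parts) >= 3 else ""
        groups = {s: data.loc[data["state"] == s, col].to_numpy() for s in STATES}
        groups = {s: g for s, g in groups.items() if g.size}
        res = anova_states(groups, n_tests=m, feature=col, band=band)
        row = {"feature": col, "band": band}
        row.update({f"mean_{s}": v for s, v in res.group_means.items()})
        row.update(
            {"F": res.f_stat, "p_raw": res.p_raw, "p_adjusted": res.p_adjusted, "n_tests": m}
        )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class DifferenceMap:
    """Signed connectivity difference (A - B) with a top-k positive-edge mask."""

    difference: np.ndarray
    mask: np.ndarray
    k: float

    def __post_init__(self) -> None:
        if self.difference.shape != self.mask.shape:
            raise ValueError("difference and mask shapes differ")
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)

    @property
    def n_retained(self) -> int:
        return int(np.triu(self.mask, k=1).sum())

    def edge_list(self) -> pd.DataFrame:
        ii, jj = np.nonzero(np.triu(self.mask, k=1))
        return pd.DataFrame(
            {"source": ii, "target": jj, "delta": self.difference[ii, jj]}
        )


def difference_top_k(
    mat_a: np.ndarray, mat_b: np.ndarray, k: float = 0.02
) -> DifferenceMap:
    """Signed difference A - B retaining the top-k fraction of increases.

    Keeps the ceil(k * n(n-1)/2) largest strictly positive differences
    (fewer if fewer positives exist); ties break lexicographically by
    (row, col) as in sparsity thresholding.
    """
    a = np.asarray(mat_a, dtype=float)
    b = np.asarray(mat_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"matrices must share a square shape, got {a.shape} vs {b.shape}")
    if not 0 < k <= 1:
        raise ValueError(f"k must lie in (0, 1], got {k}")
    diff = a - b
    n = a.shape[0]
    n_keep = int(np.ceil(k * n * (n - 1) / 2))
    ii, jj = _ranked_pairs(diff)
    mask = np.zeros_like(diff, dtype=bool)
    kept = 0
    for i, j in zip(ii, jj):
        if kept >= n_keep or diff[i, j] <= 0:
            break
        mask[i, j] = mask[j, i] = True
        kept += 1
    return DifferenceMap(diff, mask, k)


def power_cohort_spec(null: bool = False, seed: int = 0) -> CohortSpec:
    """Compact cohort used for Monte-Carlo calibration of the ANOVA stage.

    2 subjects x 8 epochs/state x 8 channels x 4 s keeps a single simulated
    cohort under a second of compute while giving the theta band enough
    cycles per epoch for a stable phase-locking estimate; state coupling
    follows the package defaults (or the identical-state null when ``null``).
    """
    from distractnet.synthetic import default_state_specs, null_state_specs

    return CohortSpec(
        n_subjects=2,
        epochs_per_state=8,
        n_channels=8,
        epoch_seconds=4.0,
        seed=seed,
        state_specs=null_state_specs() if null else default_state_specs(),
    )


@dataclass
class RejectionRates:
    """Monte-Carlo rejection rates of the corrected state contrast."""

    familywise: float
    per_band: dict[str, float]
    n_sims: int


def _epoch_band_strengths(
    spec: CohortSpec,
    estimator: str,
    bands: Sequence[str],
    sl_params: SLParams | None,
    spectral_params: SpectralParams | None,
) -> pd.DataFrame:
    cohort = generate_cohort(spec)
    rows = []
    for ep in cohort:
        decompose_bands(ep, method="fir")
        row: dict[str, object] = {"state": ep.state, "subject": ep.subject}
        for band in bands:
            sig = ep.bands[band]
            if estimator == "plv":
                mat = plv_matrix(sig, band=band)
            elif estimator == "coh":
                mat = coh_matrix(sig, ep.fs, CANONICAL_BANDS[band], spectral_params)
            elif estimator == "sl":
                mat = sl_matrix(sig, sl_params, band=band)
            else:
                raise ValueError(f"unknown estimator {estimator!r}")
            row[band] = mean_strength(mat)
        rows.append(row)
    return pd.DataFrame(rows)


def power_check(
    spec: CohortSpec,
    n_sims: int = 50,
    seed: int = 0,
    estimator: str = "plv",
    bands: Sequence[str] = BAND_ORDER,
    target_band: str = "theta",
    alpha: float = ALPHA_DEFAULT,
    sl_params: SLParams | None = None,
    spectral_params: SpectralParams | None = None,
) -> RejectionRates:
    """Simulate cohorts and measure corrected ANOVA rejection rates.

    Each simulation regenerates the cohort from ``spec`` with a fresh
    derived seed, computes per-epoch band connectivity strengths (FIR
    decomposition for speed; estimator selectable), runs the one-way
    state ANOVA per band and Bonferroni-corrects over the band family.
    Returns the familywise rate (any band rejected) and per-band rates;
    under a null cohort the familywise rate calibrates type-I error, and
    under an effect cohort ``per_band[target_band]`` measures power.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if target_band not in bands:
        raise ValueError(f"target_band {target_band!r} not in bands {list(bands)}")
    m = len(bands)
    rej = {b: 0 for b in bands}
    fam = 0
    root = np.random.SeedSequence(seed)
    sim_seeds = root.generate_state(n_sims) % (2**31)
    for s in sim_seeds:
        sim_spec = replace(spec, seed=int(s))
        table = _epoch_band_strengths(sim_spec, estimator, bands, sl_params, spectral_params)
        any_rej = False
        for band in bands:
            groups = {st: table.loc[table["state"] == st, band].to_numpy() for st in STATES}
            res = anova_states(groups, n_tests=m, feature=estimator, band=band)
            if res.p_adjusted < alpha:
                rej[band] += 1
                any_rej = True
        fam += any_rej
    return RejectionRates(
        familywise=fam / n_sims,
        per_band={b: c / n_sims for b, c in rej.items()},
        n_sims=n_sims,
    )
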