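"""Permutation and resampling machinery for strain composition analyses.

Three tests and one resampling curve:

* ``location_shuffle_test`` — are strain counts per location compatible
  with bees being randomly allocated to locations?
* ``reassortment_null`` — does the distribution of pairwise strain
  co-occurrence counts deviate from strains randomly reassorted across
  bees?  The default reassortment preserves per-bee richness and
  per-strain prevalence exactly (curveball trades); a faster
  prevalence-weighted redraw is available behind a flag but is slightly
  conservative.
* ``interspecies_association_test`` — do strains of two different markers
  (species) co-occur more or less than expected under independent
  reassortment of each?
* ``saturation_curve`` — mean number of distinct strains recovered as a
  function of the number of bees sampled.

Each test reports a chi-square discrepancy between the observed category
counts and their permutation means, but the p-value is computed from the
permutation distribution of that statistic itself,
p = (1 + #{null >= observed}) / (n_reps + 1), which is exchangeable under
the null by construction and therefore calibrated regardless of the
categories' joint distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .strain_caller import StrainTable


@dataclass
class PermutationResult:
    """Observed statistic, permutation null summary, and p-values."""

    test: str
    observed: pd.Series
    expected_mean: pd.Series
    expected_sd: pd.Series
    chi_square: float
    df: int
    p_raw: float
    n_reps: int
    seed: int
    n_tests: int = 1
    applicable: bool = True
    null_statistics: np.ndarray | None = field(default=None, repr=False)

    @property
    def p_bonferroni(self) -> float:
        return min(1.0, self.p_raw * self.n_tests)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "observed": self.observed.to_dict(),
            "expected_mean": self.expected_mean.to_dict(),
            "expected_sd": self.expected_sd.to_dict(),
            "chi_square": self.chi_square,
            "df": self.df,
            "p_raw": self.p_raw,
            "p_bonferroni": self.p_bonferroni,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "n_tests": self.n_tests,
            "applicable": self.applicable,
        }


def _chi_square(counts: np.ndarray, expected: np.ndarray) -> float:
    mask = expected > 0
    return float(np.sum((counts[mask] - expected[mask]) ** 2 / expected[mask]))


def _empirical_p(observed_stat: float, null_stats: np.ndarray) -> float:
    return float((1 + np.sum(null_stats >= observed_stat - 1e-12)) / (len(null_stats) + 1))


def _presence_matrix(table: StrainTable, marker: str) -> tuple[np.ndarray, list[str]]:
    samples = table.marker_samples(marker)
    pres = table.presence(marker)[samples]
    return pres.to_numpy(dtype=bool), samples


def location_shuffle_test(
    table: StrainTable,
    metadata: pd.DataFrame,
    marker: str,
    n_reps: int = 1000,
    seed: int = 0,
    n_tests: int = 1,
) -> PermutationResult:
    """Distinct strains per location vs random reallocation of bees.

    The null reallocates bee labels to locations uniformly at random while
    preserving location sizes, and recounts distinct strains per location.
    """
    P, samples = _presence_matrix(table, marker)
    loc_of = dict(zip(metadata["sample_id"], metadata["location"]))
    labels = np.array([loc_of[s] for s in samples])
    locs, loc_counts = np.unique(labels, return_counts=True)
    empty = [str(l) for l, c in zip(locs, loc_counts) if c == 0]
    if empty:
        warnings.warn(f"excluding empty locations: {empty}")
    locs = np.array([l for l, c in zip(locs, loc_counts) if c > 0])
    if len(locs) < 2:
        raise ValueError("need at least two locations with bees")

    def counts_for(lab: np.ndarray) -> np.ndarray:
        return np.array([P[:, lab == l].any(axis=1).sum() for l in locs], dtype=float)

    rng = np.random.default_rng(seed)
    observed = counts_for(labels)
    null_counts = np.empty((n_reps, len(locs)))
    for r in range(n_reps):
        null_counts[r] = counts_for(rng.permutation(labels))
    expected = null_counts.mean(axis=0)
    sd = null_counts.std(axis=0)
    chi = _chi_square(observed, expected)
    null_stats = np.array([_chi_square(null_counts[r], expected) for r in range(n_reps)])
    return PermutationResult(
        test="location_shuffle",
        observed=pd.Series(observed, index=locs),
        expected_mean=pd.Series(expected, index=locs),
        expected_sd=pd.Series(sd, index=locs),
        chi_square=chi,
        df=len(locs) - 1,
        p_raw=_empirical_p(chi, null_stats),
        n_reps=n_reps,
        seed=seed,
        n_tests=n_tests,
        null_statistics=null_stats,
    )


def _reassort(P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Redraw each bee's strain set, preserving richness and prevalence.

    Each bee draws its observed number of strains without replacement with
    probabilities proportional to overall strain prevalence, so per-bee
    richness is preserved exactly and prevalence in expectation.
    """
    n_strains, n_bees = P.shape
    w = P.sum(axis=1).astype(float)
    probs = w / w.sum()
    out = np.zeros_like(P)
    idx = np.arange(n_strains)
    for b in range(n_bees):
        k = int(P[:, b].sum())
        if k == 0:
            continue
        chosen = rng.choice(idx, size=k, replace=False, p=probs)
        out[chosen, b] = True
    return out


def _curveball(P: np.ndarray, rng: np.random.Generator, n_trades: int | None = None) -> np.ndarray:
    """Curveball swaps: preserve per-bee richness AND per-strain prevalence exactly."""
    out = P.copy()
    n_strains, n_bees = out.shape
    sets = [set(np.nonzero(out[:, b])[0]) for b in range(n_bees)]
    n_trades = n_trades or 5 * n_bees
    for _ in range(n_trades):
        i, j = rng.integers(0, n_bees, size=2)
        if i == j:
            continue
        only_i = list(sets[i] - sets[j])
        only_j = list(sets[j] - sets[i])
        m = min(len(only_i), len(only_j))
        if m == 0:
            continue
        k = int(rng.integers(0, m + 1))
        if k == 0:
            continue
        gi = [only_i[t] for t in rng.choice(len(only_i), size=k, replace=False)]
        gj = [only_j[t] for t in rng.choice(len(only_j), size=k, replace=False)]
        sets[i] = (sets[i] - set(gi)) | set(gj)
        sets[j] = (sets[j] - set(gj)) | set(gi)
    out[:] = False
    for b, s in enumerate(sets):
        out[list(s), b] = True
    return out


def _pair_cooccurrence_histogram(P: np.ndarray, max_count: int) -> np.ndarray:
    """Histogram over pair co-occurrence counts 0..max_count (upper triangle)."""
    B = P.astype(np.int64) @ P.T.astype(np.int64)
    iu = np.triu_indices(P.shape[0], k=1)
    vals = np.clip(B[iu], 0, max_count)
    return np.bincount(vals, minlength=max_count + 1).astype(float)


def _merge_bins(expected: np.ndarray, min_expected: float = 5.0) -> list[np.ndarray]:
    """Greedy left-to-right merge of adjacent bins until all expected >= min."""
    groups: list[list[int]] = []
    current: list[int] = []
    acc = 0.0
    for i, e in enumerate(expected):
        current.append(i)
        acc += e
        if acc >= min_expected:
            groups.append(current)
            current, acc = [], 0.0
    if current:
        if groups:
            groups[-1].extend(current)
        else:
            groups.append(current)
    return [np.array(g) for g in groups]


def _binned(counts: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    return np.array([counts[g].sum() for g in groups])


def reassortment_null(
    table: StrainTable,
    marker: str,
    n_reps: int = 1000,
    seed: int = 0,
    n_tests: int = 1,
    scheme: str = "curveball",
) -> PermutationResult:
    """Observed pairwise co-occurrence distribution vs random reassortment.

    The statistic is the histogram of pairwise co-occurrence counts over
    all strain pairs, with adjacent count categories merged until every
    null-expected category holds at least 5 pairs.  ``scheme`` selects the
    null: ``"curveball"`` (default; margin-preserving trades, so the
    observed table is exchangeable with the null draws and the empirical
    p-value is calibrated) or ``"prevalence"`` (per-bee redraw weighted by
    overall prevalence; faster but mildly conservative).
    """
    P, samples = _presence_matrix(table, marker)
    if P.shape[0] < 2 or len(samples) < 2:
        warnings.warn(f"{marker}: degenerate table, reassortment test not applicable")
        empty = pd.Series(dtype=float)
        return PermutationResult(
            test="reassortment", observed=empty, expected_mean=empty, expected_sd=empty,
            chi_square=float("nan"), df=0, p_raw=float("nan"), n_reps=n_reps,
            seed=seed, n_tests=n_tests, applicable=False,
        )
    if scheme not in ("prevalence", "curveball"):
        raise ValueError(f"unknown scheme {scheme!r}")
    shuffle = _reassort if scheme == "prevalence" else _curveball

    rng = np.random.default_rng(seed)
    max_count = len(samples)
    observed = _pair_cooccurrence_histogram(P, max_count)
    null_hists = np.empty((n_reps, max_count + 1))
    for r in range(n_reps):
        null_hists[r] = _pair_cooccurrence_histogram(shuffle(P, rng), max_count)
    expected_raw = null_hists.mean(axis=0)
    groups = _merge_bins(expected_raw)
    obs_b = _binned(observed, groups)
    exp_b = _binned(expected_raw, groups)
    sd_b = np.array([null_hists[:, g].sum(axis=1).std() for g in groups])
    chi = _chi_square(obs_b, exp_b)
    null_stats = np.array([_chi_square(_binned(null_hists[r], groups), exp_b) for r in range(n_reps)])
    labels = [f"{g[0]}" if len(g) == 1 else f"{g[0]}-{g[-1]}" for g in groups]
    return PermutationResult(
        test="reassortment",
        observed=pd.Series(obs_b, index=labels),
        expected_mean=pd.Series(exp_b, index=labels),
        expected_sd=pd.Series(sd_b, index=labels),
        chi_square=chi,
        df=max(len(groups) - 1, 1),
        p_raw=_empirical_p(chi, null_stats),
        n_reps=n_reps,
        seed=seed,
        n_tests=n_tests,
        null_statistics=null_stats,
    )


def interspecies_association_test(
    table_x: StrainTable,
    marker_x: str,
    table_y: StrainTable,
    marker_y: str,
    n_reps: int = 1000,
    seed: int = 0,
    n_tests: int = 1,
    scheme: str = "curveball",
) -> PermutationResult:
    """Cross-marker strain-pair co-occurrence vs independent reassortment.

    Strain pairs are formed across the two markers (one strain from each);
    the null reassorts both markers independently over the shared bees,
    using the same ``scheme`` options as :func:`reassortment_null`.
    """
    Px, sx = _presence_matrix(table_x, marker_x)
    Py, sy = _presence_matrix(table_y, marker_y)
    shared = sorted(set(sx) & set(sy))
    if len(shared) < 2:
        raise ValueError("the two tables share fewer than two bees")
    ix = [sx.index(s) for s in shared]
    iy = [sy.index(s) for s in shared]
    Px, Py = Px[:, ix], Py[:, iy]
    Px, Py = Px[Px.any(axis=1)], Py[Py.any(axis=1)]
    if Px.shape[0] < 1 or Py.shape[0] < 1:
        raise ValueError("no strains present in the shared bees")

    if scheme not in ("prevalence", "curveball"):
        raise ValueError(f"unknown scheme {scheme!r}")
    shuffle = _reassort if scheme == "prevalence" else _curveball

    def cross_hist(A: np.ndarray, B: np.ndarray) -> np.ndarray:
        C = A.astype(np.int64) @ B.T.astype(np.int64)
        vals = np.clip(C.ravel(), 0, len(shared))
        return np.bincount(vals, minlength=len(shared) + 1).astype(float)

    rng = np.random.default_rng(seed)
    observed = cross_hist(Px, Py)
    null_hists = np.empty((n_reps, len(shared) + 1))
    for r in range(n_reps):
        null_hists[r] = cross_hist(shuffle(Px, rng), shuffle(Py, rng))
    expected_raw = null_hists.mean(axis=0)
    groups = _merge_bins(expected_raw)
    obs_b = _binned(observed, groups)
    exp_b = _binned(expected_raw, groups)
    sd_b = np.array([null_hists[:, g].sum(axis=1).std() for g in groups])
    chi = _chi_square(obs_b, exp_b)
    null_stats = np.array([_chi_square(_binned(null_hists[r], groups), exp_b) for r in range(n_reps)])
    labels = [f"{g[0]}" if len(g) == 1 else f"{g[0]}-{g[-1]}" for g in groups]
    return PermutationResult(
        test=f"interspecies:{marker_x}-{marker_y}",
        observed=pd.Series(obs_b, index=labels),
        expected_mean=pd.Series(exp_b, index=labels),
        expected_sd=pd.Series(sd_b, index=labels),
        chi_square=chi,
        df=max(len(groups) - 1, 1),
        p_raw=_empirical_p(chi, null_stats),
        n_reps=n_reps,
        seed=seed,
        n_tests=n_tests,
        null_statistics=null_stats,
    )


@dataclass
class SaturationCurve:
    """Mean distinct strains recovered vs number of bees sampled."""

    subsample_sizes: np.ndarray
    mean_strains: np.ndarray
    n_combinations: int
    marker: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_bees": self.subsample_sizes, "mean_strains": self.mean_strains}
        )


def saturation_curve(
    table: StrainTable,
    marker: str,
    n_combinations: int = 100,
    seed: int = 0,
) -> SaturationCurve:
    """Rarefaction of strain richness over random nonredundant bee subsets.

    Each combination is a uniform random permutation of the bees; its
    prefixes give nested subsets of every size 1..N, so each realised curve
    is monotone non-decreasing and the size-N value equals the total number
    of distinct strains.  Prefixes of a uniform permutation are uniform
    k-subsets, so the mean matches independent subset resampling.
    """
    P, samples = _presence_matrix(table, marker)
    if len(samples) < 1:
        raise ValueError("need at least one bee")
    rng = np.random.default_rng(seed)
    n = len(samples)
    acc = np.zeros(n)
    for _ in range(n_combinations):
        perm = rng.permutation(n)
        cum_present = np.cumsum(P[:, perm], axis=1) > 0
        acc += cum_present.sum(axis=0)
    return SaturationCurve(
        subsample_sizes=np.arange(1, n + 1),
        mean_strains=acc / n_combinations,
        n_combinations=n_combinations,
        marker=marker,
    )
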