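"""Normalization, exact negative-binomial testing, temporal profile
classification and overlap statistics for stage-wise count matrices.

The test re-implements the classic exact-test workflow for small designs:

1. TMM-style scale factors (doubly trimmed mean of per-feature log ratios
   against a reference sample), rescaled to geometric mean 1;
2. a single common NB dispersion shared across features, estimated by the
   method of moments on library-size-adjusted counts;
3. counts quantile-adjusted to the geometric mean effective library size by
   moment-matched normal/gamma quantile mapping;
4. a two-sided exact conditional test on the split of the pooled adjusted
   count between the two groups under the NB model.

Calling uses inclusive thresholds (p <= p_thresh and |log2FC| >= lfc_thresh);
temporal profiles are classified from thresholded signs of consecutive
stage-mean log ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix

PROFILE_CATEGORIES = (
    "incremental",
    "decreasing",
    "high_low_high",
    "low_high_low",
    "irregular",
)

#: log2(1.5): smallest stage-to-stage change treated as a real move.
DEFAULT_TAU = 0.585
PSEUDO_COUNT = 0.5


@dataclass
class NormalizationFactors:
    """Per-sample scale factors with geometric mean 1 (effective library
    size = raw library size x factor)."""

    factors: dict
    ref_sample: str
    lib_sizes: dict

    def __post_init__(self) -> None:
        logs = np.log([self.factors[s] for s in self.factors])
        if abs(logs.mean()) > 1e-9:
            raise ValueError("normalization factors must have geometric mean 1")

    def effective_lib_sizes(self) -> dict:
        return {s: self.lib_sizes[s] * self.factors[s] for s in self.factors}


def _trimmed_keep(values: np.ndarray, trim: float) -> np.ndarray:
    """Boolean mask keeping the central (1 - 2*trim) mass by rank."""
    n = len(values)
    ranks = stats.rankdata(values, method="average")
    lo = np.floor(n * trim) + 1
    hi = n - np.floor(n * trim)
    return (ranks >= lo) & (ranks <= hi)


def normalize(cm: CountMatrix, logratio_trim: float = 0.3, abs_trim: float = 0.05) -> NormalizationFactors:
    """TMM-style factors against the sample whose upper quartile of relative
    expression is closest to the mean upper quartile."""
    lib = cm.lib_sizes.astype(float)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has all-zero counts")
    frac = cm.counts.astype(float).div(lib, axis=1)
    uq = frac.quantile(0.75)
    target = uq.mean()
    ref = min(cm.counts.columns, key=lambda s: (abs(uq[s] - target), s))

    factors = {}
    fr = frac[ref].to_numpy()
    for s in cm.counts.columns:
        if s == ref:
            factors[s] = 1.0
            continue
        fs = frac[s].to_numpy()
        mask = (fs > 0) & (fr > 0)
        if not mask.any():
            factors[s] = 1.0
            continue
        m = np.log2(fs[mask] / fr[mask])
        a = 0.5 * np.log2(fs[mask] * fr[mask])
        keep = _trimmed_keep(m, logratio_trim) & _trimmed_keep(a, abs_trim)
        factors[s] = float(2.0 ** m[keep].mean()) if keep.any() else float(2.0 ** m.mean())

    logs = np.log([factors[s] for s in cm.counts.columns])
    scale = np.exp(logs.mean())
    factors = {s: f / scale for s, f in factors.items()}
    return NormalizationFactors(factors, ref, dict(lib))


def cpm(cm: CountMatrix, factors: NormalizationFactors) -> pd.DataFrame:
    """Counts per million effective library size."""
    eff = pd.Series(factors.effective_lib_sizes())
    return cm.counts.astype(float).div(eff, axis=1) * 1e6


def _quantile_adjust(x: np.ndarray, mu_in: np.ndarray, mu_out: np.ndarray, phi: float) -> np.ndarray:
    """Map counts observed at mean ``mu_in`` to the scale of ``mu_out``.

    Moment-matched quantile mapping: the count's percentile under a normal
    (resp. gamma) approximation with NB variance mu + phi*mu^2 is re-expressed
    at the output mean; the two estimates are averaged. Exact when mu_in ==
    mu_out; preserves the first two NB moments otherwise.
    """
    mu_in = np.maximum(mu_in, 1e-8)
    mu_out = np.maximum(mu_out, 1e-8)
    v_in = mu_in + phi * mu_in**2
    v_out = mu_out + phi * mu_out**2
    # normal route (linear in x)
    y_norm = mu_out + np.sqrt(v_out / v_in) * (x - mu_in)
    # gamma route: matching shape/scale, quantile carried through
    shape_in = mu_in**2 / v_in
    shape_out = mu_out**2 / v_out
    u = stats.gamma.cdf(x, a=shape_in, scale=v_in / mu_in)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    y_gamma = stats.gamma.ppf(u, a=shape_out, scale=v_out / mu_out)
    return np.maximum(0.5 * (y_norm + y_gamma), 0.0)


def _moment_dispersion(y: np.ndarray, groups: list) -> float:
    """Pooled method-of-moments common dispersion from adjusted counts.

    Within each group, E[s^2] = mu + phi mu^2; phi is the df-weighted pooled
    ratio sum(s^2 - ybar)/sum(ybar^2) across features and groups.
    """
    num = 0.0
    den = 0.0
    for idx in groups:
        if len(idx) < 2:
            continue
        sub = y[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        df = len(idx) - 1
        num += df * float((v - m).sum())
        den += df * float((m**2).sum())
    return max(num / den, 0.0) if den > 0 else 0.0


def _exact_split_pvalue(sa: int, sb: int, na: int, nb: int, phi: float) -> float:
    """Two-sided exact conditional test of an even split of ``sa + sb``.

    Under the null both groups share one mean; conditionally on the total,
    the group-A sum follows the NB-split distribution (binomial in the
    Poisson limit). The p-value sums the probabilities of all splits no more
    likely than the observed one.
    """
    s = sa + sb
    if s == 0:
        return 1.0
    mu = s / (na + nb)
    if phi < 1e-10:
        k = np.arange(s + 1)
        logf = stats.binom.logpmf(k, s, na / (na + nb))
    else:
        ra, rb = na / phi, nb / phi
        pa = ra / (ra + na * mu)
        pb = rb / (rb + nb * mu)
        if s <= 20000:
            k = np.arange(s + 1)
        else:
            center = s * na / (na + nb)
            sd = np.sqrt(na * mu * (1 + phi * mu))
            lo = int(max(0, min(center - 50 * sd, sa - 5 * sd)))
            hi = int(min(s, max(center + 50 * sd, sa + 5 * sd)))
            k = np.arange(lo, hi + 1)
        logf = stats.nbinom.logpmf(k, ra, pa) + stats.nbinom.logpmf(s - k, rb, pb)
    logf -= logf.max()
    f = np.exp(logf)
    f /= f.sum()
    fobs = f[np.searchsorted(k, sa)]
    return float(min(1.0, f[f <= fobs * (1.0 + 1e-8)].sum()))


def exact_nb_test(
    cm: CountMatrix,
    stage_a: str,
    stage_b: str,
    factors: NormalizationFactors,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-feature exact NB test of ``stage_b`` against ``stage_a``.

    Returns a DataFrame with feature, comparison, log2fc (stage_b over
    stage_a, 0.5 pseudo-count), pvalue and BH-adjusted fdr. When
    ``dispersion`` is None a common dispersion is estimated by moments.
    """
    samples_a = cm.samples_in_stage(stage_a)
    samples_b = cm.samples_in_stage(stage_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("both stages need at least two replicates")
    used = samples_a + samples_b
    eff = factors.effective_lib_sizes()
    ne = np.array([eff[s] for s in used])
    ntilde = float(np.exp(np.log(ne).mean()))
    x = cm.counts[used].to_numpy(dtype=float)
    na, nb = len(samples_a), len(samples_b)
    ia = np.arange(na)
    ib = np.arange(na, na + nb)

    phat = x.sum(axis=1) / ne.sum()
    mu_obs = phat[:, None] * ne[None, :]
    mu_tgt = phat[:, None] * np.full_like(ne, ntilde)[None, :]

    if dispersion is None:
        phi = _moment_dispersion(x * (ntilde / ne), [ia, ib])
        for _ in range(2):
            y = _quantile_adjust(x, mu_obs, mu_tgt, phi)
            phi = _moment_dispersion(y, [ia, ib])
    else:
        phi = float(dispersion)
        y = _quantile_adjust(x, mu_obs, mu_tgt, phi)
    y = _quantile_adjust(x, mu_obs, mu_tgt, phi)

    sa = np.rint(y[:, ia].sum(axis=1)).astype(np.int64)
    sb = np.rint(y[:, ib].sum(axis=1)).astype(np.int64)
    pvals = np.array(
        [_exact_split_pvalue(int(a), int(b), na, nb, phi) for a, b in zip(sa, sb)]
    )
    mean_a = y[:, ia].mean(axis=1)
    mean_b = y[:, ib].mean(axis=1)
    lfc = np.log2((mean_b + PSEUDO_COUNT) / (mean_a + PSEUDO_COUNT))
    fdr = stats.false_discovery_control(pvals, method="bh")
    return pd.DataFrame(
        {
            "feature": cm.features,
            "comparison": f"{stage_a}_vs_{stage_b}",
            "log2fc": lfc,
            "pvalue": pvals,
            "fdr": fdr,
            "dispersion": phi,
        }
    )


def call_de(
    results: pd.DataFrame,
    p_thresh: float = 0.05,
    lfc_thresh: float = 1.0,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Significance calls at inclusive thresholds (p <= and |log2FC| >=).

    Adds ``significant`` and ``direction`` (up/down by the sign of log2FC for
    significant features, otherwise none); returns the significant subset
    unless ``keep_all``.
    """
    if p_thresh <= 0 or lfc_thresh < 0:
        raise ValueError("thresholds must be positive")
    out = results.copy()
    sig = (out["pvalue"] <= p_thresh) & (out["log2fc"].abs() >= lfc_thresh)
    out["significant"] = sig
    out["direction"] = np.where(
        sig, np.where(out["log2fc"] > 0, "up", "down"), "none"
    )
    return out if keep_all else out[out["significant"]].reset_index(drop=True)


def default_comparisons(cm: CountMatrix) -> list:
    return [(a, b) for a, b in combinations(cm.stages, 2)]


def classify_profiles(
    cm: CountMatrix,
    factors: NormalizationFactors,
    tau: float = DEFAULT_TAU,
    pseudo: float = PSEUDO_COUNT,
) -> pd.Series:
    """Assign each feature one of the five temporal profile categories.

    With stage-mean normalized expressions m1, m2, m3 and d_i the log2 ratios
    of consecutive means: (+,+) incremental, (-,-) decreasing, (-,+)
    high-low-high, (+,-) low-high-low; any |d| < tau breaks the pattern and
    yields irregular. Requires exactly three stages.
    """
    stages = cm.stages
    if len(stages) != 3:
        raise ValueError("profile classification is defined for exactly 3 stages")
    values = cpm(cm, factors)
    means = np.stack(
        [values[cm.samples_in_stage(st)].mean(axis=1).to_numpy() for st in stages],
        axis=1,
    )
    d1 = np.log2((means[:, 1] + pseudo) / (means[:, 0] + pseudo))
    d2 = np.log2((means[:, 2] + pseudo) / (means[:, 1] + pseudo))

    def sgn(d):
        return np.where(np.abs(d) < tau, 0, np.sign(d)).astype(int)

    table = {
        (1, 1): "incremental",
        (-1, -1): "decreasing",
        (-1, 1): "high_low_high",
        (1, -1): "low_high_low",
    }
    cats = [table.get((a, b), "irregular") for a, b in zip(sgn(d1), sgn(d2))]
    return pd.Series(cats, index=cm.counts.index, name="profile")


@dataclass
class VennPartition:
    """Exact 7-region partition of three named feature sets."""

    set_names: tuple
    regions: dict  # (bool, bool, bool) -> frozenset

    @property
    def core(self) -> frozenset:
        return self.regions[(True, True, True)]

    def membership(self) -> pd.DataFrame:
        rows = []
        for mask, ids in self.regions.items():
            for f in ids:
                rows.append({"feature": f, **dict(zip(self.set_names, mask))})
        return (
            pd.DataFrame(rows, columns=["feature", *self.set_names])
            .sort_values("feature")
            .reset_index(drop=True)
        )


def venn_overlap(de_sets: dict) -> VennPartition:
    """Three-way overlap of DE feature sets; the triple intersection is the
    core DE set carried into network construction."""
    if len(de_sets) != 3:
        raise ValueError("exactly three named sets are required")
    names = tuple(de_sets)
    sets = [set(de_sets[n]) for n in names]
    universe = set().union(*sets)
    regions = {}
    for mask in [(a, b, c) for a in (True, False) for b in (True, False) for c in (True, False)]:
        if not any(mask):
            continue
        ids = universe
        for m, s in zip(mask, sets):
            ids = ids & s if m else ids - s
        regions[mask] = frozenset(ids)
    return VennPartition(names, regions)


def merge_duplicate_matures(features, sequences) -> tuple:
    """Merge ids with identical mature sequences under the lexicographically
    first id; returns (kept ids sorted, alias map kept -> merged-away ids)."""
    features = sorted(features)
    by_seq: dict = {}
    for f in features:
        if f not in sequences or not sequences[f]:
            raise ValueError(f"no mature sequence for {f}")
        by_seq.setdefault(sequences[f].upper().replace("T", "U"), []).append(f)
    kept = []
    aliases = {}
    for members in by_seq.values():
        members = sorted(members)
        kept.append(members[0])
        if len(members) > 1:
            aliases[members[0]] = tuple(members[1:])
    return sorted(kept), aliases
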