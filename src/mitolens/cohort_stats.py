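"""Cohort statistics: hierarchical bootstrap CIs and two-sample t tests.

Cone-level measurements are nested within animals, so the bootstrap for the
between-group difference in mean OSR concentration resamples hierarchically:
each replicate draws animals with replacement within each group, then draws
cones with replacement within each drawn animal (pool sizes matching that
animal's own pool).  The CI is the percentile interval of the replicate mean
differences (0.5 and 99.5 percentiles for the default 99% level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BootstrapResult",
    "bootstrap_mean_diff",
    "two_sample_ttest",
    "significance_stars",
]


@dataclass
class BootstrapResult:
    mean_diff: float               # plug-in difference of group means (A - B)
    distribution: np.ndarray       # replicate mean differences, length n_boot
    ci: tuple                      # percentile bounds at the requested level
    ci_level: float
    seed: int
    resampling_scheme: str

    @property
    def n_boot(self) -> int:
        return len(self.distribution)

    def excludes_zero(self) -> bool:
        return not (self.ci[0] <= 0.0 <= self.ci[1])


def _group_arrays(group: dict) -> list[np.ndarray]:
    arrays = [np.asarray(v, float).ravel() for v in group.values()]
    if not arrays or any(len(a) == 0 for a in arrays):
        raise ValueError("each group needs >= 1 animal with >= 1 value")
    return arrays


def bootstrap_mean_diff(group_a: dict, group_b: dict, n_boot: int = 10_000,
                        ci_level: float = 0.99, seed: int = 0,
                        hierarchical: bool = True) -> BootstrapResult:
    """Bootstrap CI for the difference in group means (A - B).

    Groups are ``{animal_id: array of per-cone values}``.  The default scheme
    resamples animals, then cones within each drawn animal; ``hierarchical=
    False`` gives a flat cone-level resample for sensitivity analysis.
    """
    rng = np.random.default_rng(seed)
    arrays = (_group_arrays(group_a), _group_arrays(group_b))
    diffs = np.empty(n_boot)
    if hierarchical:
        for r in range(n_boot):
            means = []
            for arrs in arrays:
                picked = rng.integers(0, len(arrs), len(arrs))
                pooled = [arrs[i][rng.integers(0, len(arrs[i]), len(arrs[i]))]
                          for i in picked]
                means.append(np.concatenate(pooled).mean())
            diffs[r] = means[0] - means[1]
        scheme = "animals-then-cones"
    else:
        pooled = [np.concatenate(arrs) for arrs in arrays]
        for r in range(n_boot):
            diffs[r] = (rng.choice(pooled[0], len(pooled[0])).mean()
                        - rng.choice(pooled[1], len(pooled[1])).mean())
        scheme = "flat-cones"
    lo, hi = np.percentile(diffs, [50 * (1 - ci_level), 100 - 50 * (1 - ci_level)])
    plug_in = (np.concatenate(arrays[0]).mean() - np.concatenate(arrays[1]).mean())
    return BootstrapResult(mean_diff=float(plug_in), distribution=diffs,
                           ci=(float(lo), float(hi)), ci_level=ci_level,
                           seed=seed, resampling_scheme=scheme)


def two_sample_ttest(a, b) -> dict:
    """Classical two-sample, two-tailed t test (pooled variance).

    Degenerate samples with zero pooled variance and equal means return
    p = 1 with a flag.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    df = len(a) + len(b) - 2
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return {"t": 0.0, "p_two_tailed": 1.0, "df": df, "degenerate": True}
        return {"t": np.inf if a.mean() > b.mean() else -np.inf,
                "p_two_tailed": 0.0, "df": df, "degenerate": True}
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return {"t": float(t), "p_two_tailed": float(p), "df": df, "degenerate": False}


def significance_stars(p: float) -> str:
    """Significance tiers: * P<0.05, ** P<0.01, *** P<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
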