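"""Validation and comparison statistics for virtual spike traits.

Two analyses close the loop on the pipeline: (1) correlation of
virtually-measured traits against manual reference measurements (squared
Pearson r; correlation is unit-free, so virtual volume or surface may be
regressed against manual spike weight), and (2) pairwise comparison of the
germplasm groups (wild / landrace / cultivar) with two-sample t-tests and
the usual significance stars (* P<0.05, ** P<0.01, *** P<0.001, Ns
otherwise).  Welch's unequal-variance form is the default; the pooled form
is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "Ns"


@dataclass
class ValidationPair:
    """One trait measured both virtually and manually on the same spikes."""

    trait: str
    virtual: np.ndarray
    manual: np.ndarray

    def __post_init__(self):
        self.virtual = np.asarray(self.virtual, dtype=float)
        self.manual = np.asarray(self.manual, dtype=float)
        if self.virtual.shape != self.manual.shape or self.virtual.ndim != 1:
            raise ValueError("virtual and manual must be equal-length vectors")
        if self.virtual.size < 3:
            raise ValueError("need >= 3 paired observations")
        if np.isnan(self.virtual).any() or np.isnan(self.manual).any():
            raise ValueError("missing values are not allowed")


@dataclass
class GroupComparison:
    """Group summaries and pairwise t-test results for one trait."""

    trait: str
    means: dict[str, float]
    sds: dict[str, float]
    ns: dict[str, int]
    pairwise: list[dict]  # {group_a, group_b, t, p, stars}


def correlate(pair: ValidationPair) -> float:
    """Squared Pearson correlation r^2 between virtual and manual values."""
    if np.ptp(pair.virtual) == 0 or np.ptp(pair.manual) == 0:
        raise ValueError("constant vector: correlation undefined")
    r = np.corrcoef(pair.virtual, pair.manual)[0, 1]
    return float(r ** 2)


def compare_groups(values_by_group: dict[str, np.ndarray], trait: str,
                   welch: bool = True) -> GroupComparison:
    """Pairwise two-sample t-tests between groups with significance stars.

    ``welch=True`` (default) uses the unequal-variance Welch form;
    ``welch=False`` the pooled-variance form.  Identical samples give
    t = 0, p = 1, "Ns".
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} needs >= 2 observations")
    names = list(groups)
    pairwise = []
    for i, ga in enumerate(names):
        for gb in names[i + 1:]:
            res = sp_stats.ttest_ind(groups[ga], groups[gb], equal_var=not welch)
            t = float(res.statistic)
            p = float(res.pvalue)
            if np.isnan(t):  # both samples constant and equal
                t, p = 0.0, 1.0
            pairwise.append({"group_a": ga, "group_b": gb, "t": t, "p": p,
                             "stars": significance_stars(p)})
    return GroupComparison(
        trait=trait,
        means={g: float(v.mean()) for g, v in groups.items()},
        sds={g: float(v.std(ddof=1)) for g, v in groups.items()},
        ns={g: int(v.size) for g, v in groups.items()},
        pairwise=pairwise,
    )


def validate_traits(virtual_df: pd.DataFrame, manual_df: pd.DataFrame,
                    id_column: str = "spike_id") -> dict[str, float]:
    """r^2 per shared numeric trait column, spikes matched by id.

    Raises if any spike id is present in one table but not the other.
    """
    v_ids = set(virtual_df[id_column])
    m_ids = set(manual_df[id_column])
    if v_ids != m_ids:
        missing = sorted(v_ids.symmetric_difference(m_ids))
        raise ValueError(f"unmatched spike ids: {missing}")
    v = virtual_df.set_index(id_column).sort_index()
    m = manual_df.set_index(id_column).sort_index()
    shared = [c for c in v.columns if c in m.columns
              and np.issubdtype(v[c].dtype, np.number)
              and np.issubdtype(m[c].dtype, np.number)]
    if not shared:
        raise ValueError("no shared numeric trait columns to validate")
    return {c: correlate(ValidationPair(c, v[c].to_numpy(), m[c].to_numpy()))
            for c in shared}


def scatter_plot(pair: ValidationPair, path: str) -> None:
    """Virtual-vs-manual scatter with the r^2 annotated (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r2 = correlate(pair)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(pair.manual, pair.virtual, s=18)
    ax.set_xlabel(f"manual {pair.trait}")
    ax.set_ylabel(f"virtual {pair.trait}")
    ax.set_title(f"$r^2$ = {r2:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
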