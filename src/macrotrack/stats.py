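"""Group-level summaries and control-vs-mutant comparisons.

Interactions are counted per dataset (datasets contributing none are left
out, as they carry no measurements), summarised as mean +/- sample standard
deviation, and the pooled per-cell measurements — direction change theta_x,
time in clump TC, exit distance — are compared between groups with a
two-sample t-test (Student's pooled-variance by default, Welch optional).
The direction-change comparison supports the signed full-range mode and the
absolute-angle mode restricted to |theta_x| < 90 degrees, which isolates
changes of direction stronger than a straight pass-through but short of a
full repulsion.  No multiple-testing correction is applied; reports state
the number of tests run.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "summary_from_counts",
    "per_dataset_summary",
    "two_sample_ttest",
    "angle_comparison",
]

ALPHA = 0.05


@dataclass
class GroupSummary:
    """Per-dataset interaction counts and pooled measurements of one group."""

    group: str
    counts: dict[str, int] = field(default_factory=dict)
    thetas: list[float] = field(default_factory=list)  # radians
    tcs: list[int] = field(default_factory=list)  # frames
    exit_distances: list[float] = field(default_factory=list)  # pixels

    @property
    def n_datasets(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def mean(self) -> float | None:
        if not self.counts:
            return None
        return float(np.mean(list(self.counts.values())))

    @property
    def sd(self) -> float | None:
        """Sample standard deviation (n-1 denominator); None below n=2."""
        if len(self.counts) < 2:
            return None
        return float(np.std(list(self.counts.values()), ddof=1))


def summary_from_counts(counts, group: str = "") -> GroupSummary:
    """Summary from explicit per-dataset interaction counts.

    ``counts`` is a mapping dataset id -> count, or a sequence of counts
    (datasets then named by position).  Datasets with zero interactions are
    excluded: they contribute no measurements.
    """
    if isinstance(counts, dict):
        items = counts.items()
    else:
        items = ((f"{group or 'dataset'}{i + 1:02d}", c)
                 for i, c in enumerate(counts))
    kept = {k: int(v) for k, v in items if int(v) > 0}
    return GroupSummary(group=group, counts=kept)


def per_dataset_summary(interactions, group: str = "") -> GroupSummary:
    """Summary built from selected interactions tagged with dataset ids.

    Counts interactions per dataset and pools the per-cell measurements
    (degenerate angles are excluded from the pooled angle list).
    """
    counter: Counter = Counter()
    thetas, tcs, dists = [], [], []
    for it in interactions:
        counter[it.dataset_id] += 1
        tcs.append(it.tc)
        for cell in it.cells:
            if cell.theta is not None:
                thetas.append(cell.theta)
            if cell.exit_distance is not None:
                dists.append(cell.exit_distance)
    return GroupSummary(
        group=group,
        counts=dict(counter),
        thetas=thetas,
        tcs=tcs,
        exit_distances=dists,
    )


@dataclass
class ComparisonResult:
    """Outcome of one two-sample comparison."""

    variable: str
    filter_description: str
    n1: int
    n2: int
    t: float
    df: float
    p: float
    computable: bool = True
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.computable and not self.degenerate and self.p < ALPHA


def _not_computable(variable: str, filt: str, n1: int, n2: int) -> ComparisonResult:
    return ComparisonResult(
        variable=variable,
        filter_description=filt,
        n1=n1,
        n2=n2,
        t=math.nan,
        df=math.nan,
        p=math.nan,
        computable=False,
    )


def two_sample_ttest(
    xs,
    ys,
    equal_var: bool = True,
    variable: str = "",
    filter_description: str = "",
) -> ComparisonResult:
    """Two-sample t-test (Student's pooled-variance default, Welch optional).

    Degenerate inputs with zero variance in both samples yield t = 0, p = 1
    when the means agree, and a flagged degenerate result otherwise.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n1, n2 = len(xs), len(ys)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least two observations")
    v1, v2 = np.var(xs, ddof=1), np.var(ys, ddof=1)
    if v1 == 0 and v2 == 0:
        same = math.isclose(float(xs.mean()), float(ys.mean()))
        return ComparisonResult(
            variable=variable,
            filter_description=filter_description,
            n1=n1,
            n2=n2,
            t=0.0 if same else math.inf * np.sign(xs.mean() - ys.mean()),
            df=float(n1 + n2 - 2),
            p=1.0 if same else 0.0,
            degenerate=not same,
        )
    res = sps.ttest_ind(xs, ys, equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:  # Welch-Satterthwaite
        a, b = v1 / n1, v2 / n2
        df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
    return ComparisonResult(
        variable=variable,
        filter_description=filter_description,
        n1=n1,
        n2=n2,
        t=float(res.statistic),
        df=df,
        p=float(res.pvalue),
    )


def angle_comparison(
    control: GroupSummary,
    mutant: GroupSummary,
    mode: str = "absolute_lt90",
    equal_var: bool = True,
) -> ComparisonResult:
    """Compare the direction-change distributions of two groups.

    ``mode='full'`` compares signed angles over (-180, 180) degrees.
    ``mode='absolute_lt90'`` keeps only angles with |theta_x| strictly below
    90 degrees and compares their absolute values — the regime of a genuine
    change of direction rather than a repulsion.  A filtered sample smaller
    than two observations makes the comparison not computable.
    """
    a = np.degrees(np.asarray(control.thetas, dtype=float))
    b = np.degrees(np.asarray(mutant.thetas, dtype=float))
    if mode == "full":
        filt = "signed theta_x in (-180, 180) deg"
    elif mode == "absolute_lt90":
        a = np.abs(a[np.abs(a) < 90.0])
        b = np.abs(b[np.abs(b) < 90.0])
        filt = "|theta_x| < 90 deg, absolute values"
    else:
        raise ValueError("mode must be 'full' or 'absolute_lt90'")
    if len(a) < 2 or len(b) < 2:
        return _not_computable("theta_x", filt, len(a), len(b))
    return two_sample_ttest(
        a, b, equal_var=equal_var, variable="theta_x", filter_description=filt
    )
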