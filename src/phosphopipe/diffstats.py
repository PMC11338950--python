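"""Two-group differential phosphorylation analysis.

The core statistic is a pooled-variance (Student's) two-sample t-test per
site, run by default on log2-transformed calibrated ratios, combined with a
linear-scale fold change (group-B mean over group-A mean). A site is called
"up" when p < alpha and FC >= fc_threshold, "down" when p < alpha and
FC <= 1/fc_threshold, otherwise "ns". Benjamini-Hochberg q-values are
reported alongside but the direction calls use the raw p, matching the common
volcano-plot convention.

Organised statsmodels-style: :class:`SiteDifferentialModel` is built from a
calibrated matrix plus a study design, and ``fit()`` returns a
:class:`DifferentialResults` carrying the per-site estimates, direction
counts, protein-level aggregation and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import StudyDesign
from .preprocess import QuantMatrix

logger = logging.getLogger(__name__)


@dataclass
class DiffSiteResult:
    """Fold change, p value and direction call for one site."""

    site_id: str
    mean_a: float
    mean_b: float
    fold_change: float
    t_stat: float
    p_value: float
    q_value: float
    direction: str  # up | down | ns
    n_a: int
    n_b: int
    reason: str = "ok"  # ok | insufficient_data | nonpositive_mean


@dataclass
class ProteinDirectionSummary:
    protein_accession: str
    n_up_sites: int
    n_down_sites: int
    category: str  # up-only | down-only | both | none


def ttest_two_group(
    a: Sequence[float], b: Sequence[float], log_scale: bool = True
) -> tuple[float, float]:
    """Pooled-variance two-sided t-test between two groups of intensities.

    With ``log_scale`` (default) values are log2-transformed first, which is
    the natural scale for multiplicative TMT ratios. Degenerate inputs follow
    a fixed contract: both groups zero-variance with equal means -> (0, 1);
    zero pooled variance with unequal means -> (+/-inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if log_scale:
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("log-scale t-test requires positive values")
        a = np.log2(a)
        b = np.log2(b)
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise ValueError(f"each group needs >= 2 values (got {n_a}, {n_b})")
    ma, mb = a.mean(), b.mean()
    sp2 = ((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)) / (n_a + n_b - 2)
    if sp2 == 0.0:
        if ma == mb:
            return 0.0, 1.0
        return math.copysign(math.inf, mb - ma), 0.0
    t = (mb - ma) / math.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    p = 2.0 * stats.t.sf(abs(t), df=n_a + n_b - 2)
    return float(t), float(p)


def fold_change(mean_a: float, mean_b: float) -> float:
    """Linear-scale fold change of group B over group A."""
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError(f"means must be positive, got {mean_a}, {mean_b}")
    return mean_b / mean_a


class SiteDifferentialModel:
    """Per-site two-group differential phosphorylation model.

    Parameters
    ----------
    matrix
        Calibrated (or normalized) site x channel :class:`QuantMatrix`.
    design
        Channel -> group/replicate map.
    group_a, group_b
        Reference and comparison group labels (e.g. caput vs cauda); fold
        changes are group_b over group_a.
    log_scale
        Run the t-test on log2 values (default) or on the linear scale.
    """

    def __init__(
        self,
        matrix: QuantMatrix,
        design: StudyDesign,
        group_a: str,
        group_b: str,
        log_scale: bool = True,
    ):
        for g in (group_a, group_b):
            if g not in design.groups:
                raise ValueError(f"unknown group label {g!r}")
        if len(design.channels_for(group_a)) < 2 or len(design.channels_for(group_b)) < 2:
            raise ValueError("both groups need >= 2 channels")
        self.matrix = matrix
        self.design = design
        self.group_a = group_a
        self.group_b = group_b
        self.log_scale = log_scale

    def fit(self, alpha: float = 0.05, fc_threshold: float = 1.5) -> "DifferentialResults":
        data = self.matrix.data
        A = data[self.design.channels_for(self.group_a)].to_numpy(dtype=float)
        B = data[self.design.channels_for(self.group_b)].to_numpy(dtype=float)
        if self.log_scale:
            # nonpositive calibrated values cannot be log-ratios; treat as missing
            A = np.where(A > 0, A, np.nan)
            B = np.where(B > 0, B, np.nan)

        n_a = np.sum(~np.isnan(A), axis=1)
        n_b = np.sum(~np.isnan(B), axis=1)
        mean_a = np.nanmean(np.where(np.isnan(A), np.nan, A), axis=1)
        mean_b = np.nanmean(np.where(np.isnan(B), np.nan, B), axis=1)

        if self.log_scale:
            TA, TB = np.log2(A), np.log2(B)
        else:
            TA, TB = A, B
        import warnings

        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            # rows with <2 values per group are reported as insufficient_data
            warnings.simplefilter("ignore", category=RuntimeWarning)
            ma = np.nanmean(TA, axis=1)
            mb = np.nanmean(TB, axis=1)
            va = np.nanvar(TA, axis=1, ddof=1)
            vb = np.nanvar(TB, axis=1, ddof=1)
        testable = (n_a >= 2) & (n_b >= 2)
        df_ = n_a + n_b - 2
        sp2 = np.where(testable, ((n_a - 1) * va + (n_b - 1) * vb) / np.maximum(df_, 1), np.nan)
        se = np.sqrt(sp2 * (1.0 / np.maximum(n_a, 1) + 1.0 / np.maximum(n_b, 1)))
        with np.errstate(invalid="ignore", divide="ignore"):
            t = (mb - ma) / se
        p = np.full(len(data), np.nan)
        ok = testable & (sp2 > 0)
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=df_[ok])
        # degenerate: zero pooled variance
        degen = testable & (sp2 == 0)
        eq = degen & (ma == mb)
        ne = degen & (ma != mb)
        t[eq], p[eq] = 0.0, 1.0
        t[ne] = np.where(mb[ne] > ma[ne], np.inf, -np.inf)
        p[ne] = 0.0

        with np.errstate(invalid="ignore", divide="ignore"):
            fc = np.where((mean_a > 0) & (mean_b > 0), mean_b / mean_a, np.nan)

        tested = ~np.isnan(p)
        q = np.full(len(data), np.nan)
        if tested.any():
            from statsmodels.stats.multitest import multipletests

            q[tested] = multipletests(p[tested], method="fdr_bh")[1]

        direction = np.full(len(data), "ns", dtype=object)
        callable_ = tested & ~np.isnan(fc)
        direction[callable_ & (p < alpha) & (fc >= fc_threshold)] = "up"
        direction[callable_ & (p < alpha) & (fc <= 1.0 / fc_threshold)] = "down"

        reason = np.full(len(data), "ok", dtype=object)
        reason[~testable] = "insufficient_data"
        reason[testable & np.isnan(fc)] = "nonpositive_mean"

        frame = pd.DataFrame(
            {
                "site_id": data.index,
                "n_a": n_a,
                "n_b": n_b,
                "mean_a": mean_a,
                "mean_b": mean_b,
                "fold_change": fc,
                "log2fc": np.log2(fc),
                "t_stat": t,
                "p_value": p,
                "q_value": q,
                "direction": direction,
                "reason": reason,
            }
        ).reset_index(drop=True)
        logger.info(
            "differential %s vs %s: %d up, %d down, %d ns of %d sites",
            self.group_a,
            self.group_b,
            int((direction == "up").sum()),
            int((direction == "down").sum()),
            int((direction == "ns").sum()),
            len(frame),
        )
        return DifferentialResults(self, frame, alpha, fc_threshold)


class DifferentialResults:
    """Per-site differential phosphorylation estimates and direction calls."""

    def __init__(
        self,
        model: SiteDifferentialModel,
        frame: pd.DataFrame,
        alpha: float,
        fc_threshold: float,
    ):
        self.model = model
        self.frame = frame
        self.alpha = alpha
        self.fc_threshold = fc_threshold

    # -- counts -----------------------------------------------------------
    @property
    def n_up(self) -> int:
        return int((self.frame["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.frame["direction"] == "down").sum())

    @property
    def n_ns(self) -> int:
        return int((self.frame["direction"] == "ns").sum())

    @property
    def n_tested(self) -> int:
        return int(self.frame["p_value"].notna().sum())

    # -- id sets ----------------------------------------------------------
    def direction_ids(self, direction: str) -> frozenset[str]:
        return frozenset(self.frame.loc[self.frame["direction"] == direction, "site_id"])

    def p_only_ids(self, direction: str, alpha: float | None = None) -> frozenset[str]:
        """Significant-by-p-only sets (no fold-change filter): ``up`` means
        FC > 1, ``down`` means FC < 1."""
        alpha = self.alpha if alpha is None else alpha
        f = self.frame
        sig = f["p_value"].notna() & (f["p_value"] < alpha)
        if direction == "up":
            mask = sig & (f["fold_change"] > 1)
        elif direction == "down":
            mask = sig & (f["fold_change"] < 1)
        else:
            raise ValueError(f"direction must be up/down, got {direction!r}")
        return frozenset(f.loc[mask, "site_id"])

    def tested_ids(self) -> frozenset[str]:
        return frozenset(self.frame.loc[self.frame["p_value"].notna(), "site_id"])

    def to_records(self) -> list[DiffSiteResult]:
        return [
            DiffSiteResult(
                site_id=r.site_id,
                mean_a=r.mean_a,
                mean_b=r.mean_b,
                fold_change=r.fold_change,
                t_stat=r.t_stat,
                p_value=r.p_value,
                q_value=r.q_value,
                direction=r.direction,
                n_a=int(r.n_a),
                n_b=int(r.n_b),
                reason=r.reason,
            )
            for r in self.frame.itertuples(index=False)
        ]

    def aggregate_proteins(
        self, parent_of: Mapping[str, str]
    ) -> list[ProteinDirectionSummary]:
        return aggregate_proteins(self.to_records(), parent_of)

    def summary(self) -> str:
        lines = [
            "Differential phosphorylation summary",
            "=" * 44,
            f"comparison        : {self.model.group_a} -> {self.model.group_b}",
            f"scale             : {'log2' if self.model.log_scale else 'linear'} t-test, "
            f"linear FC",
            f"thresholds        : p < {self.alpha}, FC >= {self.fc_threshold}",
            f"sites             : {len(self.frame)}",
            f"tested            : {self.n_tested}",
            f"significant (p)   : {int((self.frame['p_value'] < self.alpha).sum())}",
            f"up (p & FC)       : {self.n_up}",
            f"down (p & FC)     : {self.n_down}",
            f"ns                : {self.n_ns}",
        ]
        return "\n".join(lines)


def classify_sites(
    calibrated: QuantMatrix,
    design: StudyDesign,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
    log_scale: bool = True,
) -> list[DiffSiteResult]:
    """Functional wrapper: fit the differential model and return site records."""
    model = SiteDifferentialModel(calibrated, design, group_a, group_b, log_scale)
    return model.fit(alpha=alpha, fc_threshold=fc_threshold).to_records()


def aggregate_proteins(
    results: Iterable[DiffSiteResult], parent_of: Mapping[str, str]
) -> list[ProteinDirectionSummary]:
    """Roll up site direction calls to per-protein up/down counts.

    Every significant site must map to a protein; unmapped significant sites
    are an error (listing the offending ids).
    """
    results = list(results)
    unmapped = [
        r.site_id
        for r in results
        if r.direction in ("up", "down") and r.site_id not in parent_of
    ]
    if unmapped:
        raise ValueError(f"significant sites without protein mapping: {unmapped}")
    counts: dict[str, list[int]] = {}
    for r in results:
        acc = parent_of.get(r.site_id)
        if acc is None:
            continue
        c = counts.setdefault(acc, [0, 0])
        if r.direction == "up":
            c[0] += 1
        elif r.direction == "down":
            c[1] += 1
    out = []
    for acc, (n_up, n_down) in counts.items():
        if n_up and n_down:
            cat = "both"
        elif n_up:
            cat = "up-only"
        elif n_down:
            cat = "down-only"
        else:
            cat = "none"
        out.append(ProteinDirectionSummary(acc, n_up, n_down, cat))
    return out


def overlap_fraction(
    set_a: Iterable[str], set_b: Iterable[str]
) -> tuple[int, float, float]:
    """Intersection count, fraction of ``set_a``, and percentage (1 decimal)."""
    set_a = frozenset(set_a)
    set_b = frozenset(set_b)
    if not set_a:
        raise ValueError("set_a must be nonempty")
    n = len(set_a & set_b)
    frac = n / len(set_a)
    return n, frac, round(100.0 * frac, 1)


def overlap_with_proteome(
    phospho_up_proteins: Iterable[str],
    phospho_down_proteins: Iterable[str],
    prot_up: Iterable[str],
    prot_down: Iterable[str],
) -> dict[str, int]:
    """Cross-tabulate phospho-regulated proteins against proteome DE proteins."""
    pu, pdn = frozenset(phospho_up_proteins), frozenset(phospho_down_proteins)
    eu, edn = frozenset(prot_up), frozenset(prot_down)
    return {
        "phospho_up_prot_up": len(pu & eu),
        "phospho_up_prot_down": len(pu & edn),
        "phospho_down_prot_up": len(pdn & eu),
        "phospho_down_prot_down": len(pdn & edn),
    }
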