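"""Volume normalization, MoCA stratification, and the volumetric group comparison.

The exploratory analysis normalizes hippocampal volume by total intracranial
volume (ICV), splits the PD group at the conventional MoCA impairment
threshold (scores strictly below 26), and compares normalized volumes across
the three strata (PD below threshold, PD at/above threshold, HC) with a
one-way ANOVA followed by Fisher's LSD post-hoc pairwise tests. Fisher's LSD
uses the ANOVA's pooled within-group mean square and applies no multiplicity
adjustment — that is its definition — and is reported alongside the omnibus
p-value regardless of omnibus significance.

By default the bilateral (left + right) hippocampal volume enters the
comparison; a flag selects a single side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from rdflib import Graph
from scipy import stats as sps

from .simulate import MOCA_THRESHOLD
from .store import run_sparql

__all__ = [
    "VolumeRecord",
    "AnovaResult",
    "LsdResult",
    "GroupComparison",
    "normalize_volume",
    "stratify_by_threshold",
    "one_way_anova",
    "fisher_lsd",
    "extract_analysis_frame",
    "run_group_comparison",
]

STRATA = ("PD_below", "PD_at_or_above", "HC")


def normalize_volume(volume_mm3: float, icv_mm3: float) -> float:
    """Dimensionless volume ratio: structure volume / total intracranial volume."""
    if volume_mm3 <= 0 or icv_mm3 <= 0:
        raise ValueError(
            f"volumes must be positive: volume={volume_mm3}, icv={icv_mm3}"
        )
    if volume_mm3 >= icv_mm3:
        warnings.warn(
            f"implausible volumes: structure volume {volume_mm3} >= ICV {icv_mm3}",
            stacklevel=2,
        )
    return volume_mm3 / icv_mm3


@dataclass(frozen=True)
class VolumeRecord:
    """One region volume with its ICV and normalized ratio."""

    subject_id: str
    region: str
    volume_mm3: float
    icv_mm3: float

    def __post_init__(self) -> None:
        if self.region not in ("left_hippocampus", "right_hippocampus"):
            raise ValueError(f"unknown region {self.region!r}")

    @property
    def normalized(self) -> float:
        return normalize_volume(self.volume_mm3, self.icv_mm3)


def stratify_by_threshold(
    frame: pd.DataFrame,
    threshold: float = MOCA_THRESHOLD,
    score_column: str = "moca_total",
    group_column: str = "group_label",
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Partition subjects into PD_below / PD_at_or_above / HC strata.

    PD subjects split strictly below vs at-or-above the threshold; HC stays
    one stratum regardless of score. Subjects missing group or score are
    excluded and returned separately — the strata plus exclusions are a
    disjoint partition of the input rows.
    """
    has_info = frame[group_column].isin(["PD", "HC"]) & frame[score_column].notna()
    excluded = frame[~has_info]
    usable = frame[has_info]
    pd_rows = usable[usable[group_column] == "PD"]
    strata = {
        "PD_below": pd_rows[pd_rows[score_column] < threshold],
        "PD_at_or_above": pd_rows[pd_rows[score_column] >= threshold],
        "HC": usable[usable[group_column] == "HC"],
    }
    return strata, excluded


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    group_ns: dict[str, int]
    ms_within: float
    grand_mean: float
    degenerate: bool = False


def one_way_anova(
    groups: list[np.ndarray] | list[list[float]],
    labels: list[str] | None = None,
) -> AnovaResult:
    """Fixed-effects one-way ANOVA from sums of squares.

    F = [Σ nᵢ(meanᵢ − grand)² / (k−1)] / [Σᵢⱼ (xᵢⱼ − meanᵢ)² / (N−k)],
    with the p-value from the F(k−1, N−k) distribution. Zero within-group
    variance with unequal means is flagged degenerate (F = +inf, p = 0).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for i, arr in enumerate(arrays):
        if arr.size < 2:
            raise ValueError(f"group {i} has n={arr.size}; need n >= 2 per group")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {i} contains non-finite values")
    labels = labels if labels is not None else [f"group{i}" for i in range(len(arrays))]

    k = len(arrays)
    ns = np.array([a.size for a in arrays])
    n_total = int(ns.sum())
    means = np.array([a.mean() for a in arrays])
    grand = float(np.concatenate(arrays).mean())

    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((a - m) ** 2) for a, m in zip(arrays, means)))
    df_between, df_within = k - 1, n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within

    if ms_within == 0:
        if ss_between == 0:
            f_stat, p, degenerate = 0.0, 1.0, True
        else:
            f_stat, p, degenerate = float("inf"), 0.0, True
    else:
        f_stat = ms_between / ms_within
        p = float(sps.f.sf(f_stat, df_between, df_within))
        degenerate = False

    return AnovaResult(
        F=f_stat,
        df_between=df_between,
        df_within=df_within,
        p=p,
        group_means=dict(zip(labels, means.tolist())),
        group_ns=dict(zip(labels, ns.tolist())),
        ms_within=ms_within,
        grand_mean=grand,
        degenerate=degenerate,
    )


@dataclass
class LsdResult:
    """Unadjusted pairwise comparisons with pooled within-group variance."""

    pairs: list[tuple[str, str, float, float, float]]  # (i, j, mean diff, t, p)
    df: int
    degenerate: bool = False

    def p_value(self, a: str, b: str) -> float:
        for i, j, _, _, p in self.pairs:
            if {i, j} == {a, b}:
                return p
        raise KeyError((a, b))


def fisher_lsd(
    groups: list[np.ndarray] | list[list[float]],
    anova: AnovaResult,
    labels: list[str] | None = None,
) -> LsdResult:
    """Fisher's LSD: every pairwise t uses the ANOVA's MSW and df_within.

    t = (meanᵢ − meanⱼ) / sqrt(MSW · (1/nᵢ + 1/nⱼ)), two-sided p from the t
    distribution with N−k degrees of freedom; no multiplicity adjustment.
    """
    labels = labels if labels is not None else list(anova.group_means)
    if sorted(labels) != sorted(anova.group_means):
        raise ValueError("labels do not match the ANOVA groups")
    means = anova.group_means
    ns = anova.group_ns
    if anova.ms_within == 0:
        pairs = [
            (a, b, means[a] - means[b], float("nan"), float("nan"))
            for a, b in combinations(labels, 2)
        ]
        return LsdResult(pairs=pairs, df=anova.df_within, degenerate=True)
    pairs = []
    for a, b in combinations(labels, 2):
        diff = means[a] - means[b]
        se = np.sqrt(anova.ms_within * (1.0 / ns[a] + 1.0 / ns[b]))
        t_stat = diff / se
        p = float(2.0 * sps.t.sf(abs(t_stat), anova.df_within))
        pairs.append((a, b, float(diff), float(t_stat), p))
    return LsdResult(pairs=pairs, df=anova.df_within)


# ---------------------------------------------------------------------------
# knowledge-graph extraction and the end-to-end comparison

# Per-subject facets are pulled with separate chain-shaped queries and merged
# in pandas: each query's pattern chains through shared variables, which keeps
# naive bottom-up SPARQL evaluation linear in the number of subjects.
_PREFIXES = """
PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX obo: <http://purl.obolibrary.org/obo/>
PREFIX nkg: <https://w3id.org/neurokg/onto/>
"""

_SUBJECTS_QUERY = _PREFIXES + """
SELECT ?s ?grp ?src WHERE {
    ?s rdf:type obo:NCBITaxon_9606 .
    ?s rdf:type ?grp .
    FILTER (?grp IN (nkg:NKG_0000060, nkg:NKG_0000061))
    OPTIONAL { ?s nkg:NKG_0000080 ?src . }
} ORDER BY ?s
"""

_MOCA_QUERY = _PREFIXES + """
SELECT ?s ?moca WHERE {
    ?assay rdf:type obo:NPT_0020000 .
    ?assay obo:BFO_0000057 ?s .
    ?assay obo:OBI_0000299 ?out .
    ?out obo:OBI_0001938 ?vs .
    ?vs obo:OBI_0002135 ?moca .
} ORDER BY ?s
"""

# datum class → (value variable, datum-to-subject anatomy path)
_VOLUME_QUERY = _PREFIXES + """
SELECT ?s ?value WHERE {
    ?datum rdf:type <%s> .
    ?datum obo:IAO_0000136 ?region .
    %s
    ?datum obo:OBI_0001938 ?vs .
    ?vs obo:OBI_0002135 ?value .
} ORDER BY ?s
"""
_HIPPO_PATH = "?region obo:BFO_0000050 ?brain . ?brain obo:BFO_0000050 ?s ."
_BRAIN_PATH = "?region obo:BFO_0000050 ?s ."

_GROUP_LABELS = {
    "https://w3id.org/neurokg/onto/NKG_0000060": "PD",
    "https://w3id.org/neurokg/onto/NKG_0000061": "HC",
}


def _value_by_subject(graph: Graph, query: str, var: str) -> dict[str, float]:
    return {
        str(row["s"]): float(row[var])
        for row in run_sparql(graph, query).rows
        if row.get(var) is not None
    }


def extract_analysis_frame(graph: Graph) -> pd.DataFrame:
    """Pull per-subject group, MoCA total, volumes, and ICV out of the graph.

    Returns one row per subject with a ``normalized`` column holding the
    ICV-normalized bilateral hippocampal volume (and per-side ratios).
    """
    moca = _value_by_subject(graph, _MOCA_QUERY, "moca")
    left = _value_by_subject(
        graph, _VOLUME_QUERY % ("https://w3id.org/neurokg/onto/NKG_0000031", _HIPPO_PATH),
        "value",
    )
    right = _value_by_subject(
        graph, _VOLUME_QUERY % ("https://w3id.org/neurokg/onto/NKG_0000032", _HIPPO_PATH),
        "value",
    )
    icv = _value_by_subject(
        graph, _VOLUME_QUERY % ("https://w3id.org/neurokg/onto/NKG_0000033", _BRAIN_PATH),
        "value",
    )
    records = []
    for row in run_sparql(graph, _SUBJECTS_QUERY).rows:
        group = _GROUP_LABELS.get(str(row.get("grp")))
        if group is None:
            continue
        subject = str(row["s"])
        records.append(
            {
                "subject": subject,
                "source": str(row["src"]) if row.get("src") is not None else None,
                "group_label": group,
                "moca_total": moca.get(subject, np.nan),
                "left_volume_mm3": left.get(subject, np.nan),
                "right_volume_mm3": right.get(subject, np.nan),
                "icv_mm3": icv.get(subject, np.nan),
            }
        )
    frame = pd.DataFrame.from_records(records).drop_duplicates(subset="subject")
    if frame.empty:
        return frame
    for column, sides in (
        ("normalized", ("left_volume_mm3", "right_volume_mm3")),
        ("normalized_left", ("left_volume_mm3",)),
        ("normalized_right", ("right_volume_mm3",)),
    ):
        total = sum(frame[s] for s in sides)
        frame[column] = total / frame["icv_mm3"]
    return frame.reset_index(drop=True)


@dataclass
class GroupComparison:
    """Stratified ANOVA + Fisher's LSD on normalized hippocampal volume."""

    strata_ns: dict[str, int]
    anova: AnovaResult
    lsd: LsdResult
    excluded: int
    volume: str = "bilateral"

    def to_dict(self) -> dict:
        return {
            "volume": self.volume,
            "strata_n": self.strata_ns,
            "excluded": self.excluded,
            "anova": {
                "F": self.anova.F,
                "df_between": self.anova.df_between,
                "df_within": self.anova.df_within,
                "p": self.anova.p,
                "group_means": self.anova.group_means,
                "ms_within": self.anova.ms_within,
            },
            "lsd": [
                {"group_i": a, "group_j": b, "mean_diff": d, "t": t, "p": p}
                for a, b, d, t, p in self.lsd.pairs
            ],
        }

    def to_text(self) -> str:
        lines = [
            f"One-way ANOVA on ICV-normalized {self.volume} hippocampal volume",
            f"  strata: "
            + ", ".join(f"{k} (n={v})" for k, v in self.strata_ns.items()),
            f"  F({self.anova.df_between}, {self.anova.df_within}) = "
            f"{self.anova.F:.3f}, p = {self.anova.p:.4f}",
            "  group means (normalized volume):",
        ]
        for label, mean in self.anova.group_means.items():
            lines.append(f"    {label}: {mean:.6f}")
        lines.append("  Fisher's LSD pairwise comparisons (unadjusted):")
        for a, b, diff, t_stat, p in self.lsd.pairs:
            lines.append(
                f"    {a} vs {b}: diff = {diff:+.6f}, t = {t_stat:.3f}, p = {p:.4f}"
            )
        if self.excluded:
            lines.append(f"  excluded (missing group/score): {self.excluded}")
        return "\n".join(lines)


def run_group_comparison(
    frame: pd.DataFrame,
    threshold: float = MOCA_THRESHOLD,
    volume: str = "bilateral",
) -> GroupComparison:
    """Stratify by MoCA threshold and compare normalized volumes across strata."""
    column = {
        "bilateral": "normalized",
        "left": "normalized_left",
        "right": "normalized_right",
    }[volume]
    usable = frame[frame[column].notna()]
    strata, excluded = stratify_by_threshold(usable, threshold=threshold)
    groups = [strata[name][column].to_numpy(dtype=float) for name in STRATA]
    anova = one_way_anova(groups, labels=list(STRATA))
    lsd = fisher_lsd(groups, anova, labels=list(STRATA))
    return GroupComparison(
        strata_ns={name: int(len(strata[name])) for name in STRATA},
        anova=anova,
        lsd=lsd,
        excluded=int(len(excluded) + (len(frame) - len(usable))),
        volume=volume,
    )
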