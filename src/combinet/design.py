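"""Inter-cluster combination design from drug communities.

The working hypothesis: pairing potent drugs drawn from *different* DSN
communities hits complementary vulnerability profiles, so those cross-cluster
("positive") pairs should out-synergise within-cluster ("negative") pairs.
This module ranks drugs inside each community by median viability, enumerates
the positive/negative pair sets for the top-k drugs, and tests whether the
positive group's synergy distribution exceeds the negative group's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DesignSet", "rank_drugs", "build_design", "compare_groups"]


def _norm_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class DesignSet:
    """Positive (cross-cluster) and negative (within-cluster) drug pairs."""

    positive_pairs: list[tuple[str, str]]
    negative_pairs: list[tuple[str, str]]
    k: int
    cell_lines: list[str] = field(default_factory=list)
    top_drugs: dict[int, list[str]] = field(default_factory=dict)

    @property
    def n_triplets(self) -> int:
        n_pairs = len(self.positive_pairs) + len(self.negative_pairs)
        return n_pairs * max(1, len(self.cell_lines))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        cells = self.cell_lines or [None]
        for group, pairs in (("positive", self.positive_pairs), ("negative", self.negative_pairs)):
            for a, b in pairs:
                for cl in cells:
                    rows.append({"drug_a": a, "drug_b": b, "group": group, "cell_line": cl})
        return pd.DataFrame(rows)


def rank_drugs(members: Sequence[str], potency: Mapping[str, float]) -> list[str]:
    """Cluster members ordered most-potent first (ascending median viability).

    Ties broken by drug id; a drug without a potency value is an error.
    """
    missing = [d for d in members if d not in potency or pd.isna(potency[d])]
    if missing:
        raise ValueError(f"no potency for drugs: {sorted(missing)}")
    return sorted(members, key=lambda d: (potency[d], d))


def build_design(
    clusters: Mapping[int, Sequence[str]],
    potency: Mapping[str, float],
    k: int = 5,
    cell_lines: Sequence[str] | None = None,
) -> DesignSet:
    """Top-k-per-cluster positive/negative pair enumeration.

    For two clusters: k² positive cross pairs and 2·C(k,2) negative within
    pairs.  More than two clusters generalise to all cross products over
    cluster pairs.  A cluster smaller than k shrinks its own top list with a
    warning.  Pairs are unordered and contain no self-pairs.
    """
    import warnings

    if len(clusters) < 2:
        raise ValueError("design needs at least 2 drug clusters")
    tops: dict[int, list[str]] = {}
    for c, members in sorted(clusters.items()):
        kk = min(k, len(members))
        if kk < k:
            warnings.warn(f"cluster {c} has only {kk} < k={k} members; k reduced")
        tops[int(c)] = rank_drugs(members, potency)[:kk]
    positive: list[tuple[str, str]] = []
    for c1, c2 in combinations(sorted(tops), 2):
        positive.extend(_norm_pair(a, b) for a in tops[c1] for b in tops[c2] if a != b)
    negative: list[tuple[str, str]] = []
    for c in sorted(tops):
        negative.extend(_norm_pair(a, b) for a, b in combinations(tops[c], 2))
    return DesignSet(
        positive_pairs=sorted(set(positive)),
        negative_pairs=sorted(set(negative)),
        k=k,
        cell_lines=list(cell_lines or []),
        top_drugs=tops,
    )


def compare_groups(
    scores: Mapping[tuple[str, str], Sequence[float] | float] | pd.DataFrame,
    design: DesignSet,
    test: str = "t",
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Positive-vs-negative synergy comparison, one row per synergy measure.

    ``scores`` maps unordered pairs to synergy values — either a single value
    or one per cell line — or is a DataFrame with columns drug_a, drug_b and
    one column per synergy measure.  ``test`` is "t" (Student, Welch variant)
    or "wilcoxon" (rank-sum); one-sided tests take alternative="greater" to
    ask whether the positive group scores higher.
    """
    if test not in ("t", "wilcoxon"):
        raise ValueError(f"unknown test: {test!r}")
    if isinstance(scores, pd.DataFrame):
        measures = [c for c in scores.columns if c not in ("drug_a", "drug_b", "cell_line", "sample_id", "group")]
        table = scores.copy()
        table["_pair"] = [_norm_pair(a, b) for a, b in zip(table["drug_a"], table["drug_b"])]
    else:
        flat = []
        for pair, vals in scores.items():
            vals = np.atleast_1d(np.asarray(vals, dtype=float))
            for v in vals:
                flat.append({"_pair": _norm_pair(*pair), "score": v})
        table = pd.DataFrame(flat)
        measures = ["score"]

    pos = set(design.positive_pairs)
    neg = set(design.negative_pairs)
    rows = []
    for m in measures:
        pv = table.loc[table["_pair"].isin(pos), m].dropna().to_numpy()
        nv = table.loc[table["_pair"].isin(neg), m].dropna().to_numpy()
        if len(pv) < 2 or len(nv) < 2:
            raise ValueError(f"empty or near-empty group for measure {m!r}")
        if test == "t":
            stat, p = stats.ttest_ind(pv, nv, equal_var=False, alternative=alternative)
        else:
            stat, p = stats.mannwhitneyu(pv, nv, alternative=alternative)
        rows.append({
            "measure": m,
            "test": test,
            "alternative": alternative,
            "statistic": float(stat),
            "p": float(p),
            "positive_mean": float(pv.mean()),
            "negative_mean": float(nv.mean()),
            "positive_median": float(np.median(pv)),
            "negative_median": float(np.median(nv)),
            "n_positive": len(pv),
            "n_negative": len(nv),
        })
    return pd.DataFrame(rows)
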