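"""Intra-cluster homogeneity of drug and sample communities.

A community structure found purely from potency profiles is corroborated
against independent evidence: chemical structure (Dice similarity of circular
fingerprints), shared protein targets (direct and 2-hop "secondary" targets
in a signalling network), shared pathways, expression similarity (harmonic
similarity for signed values, continuous Jaccard distance for counts) and
damaging-mutation frequency profiles.  Each within-cluster pairwise statistic
is compared against a random-grouping permutation null with Kruskal–Wallis
and pairwise Wilcoxon rank-sum tests under Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Fingerprint",
    "HomogeneityReport",
    "dice_similarity",
    "fingerprints_from_smiles",
    "pairwise_set_intersections",
    "secondary_targets",
    "pathway_intersections",
    "harmonic_similarity",
    "jaccard_distance",
    "random_grouping_null",
    "compare_distributions",
    "mutation_profile",
]


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary substructure fingerprint (e.g. 2048-bit ECFP4)."""

    bits: np.ndarray
    source: str | None = None

    def __post_init__(self):
        bits = np.asarray(self.bits).astype(bool)
        object.__setattr__(self, "bits", bits)

    @property
    def n_on(self) -> int:
        return int(self.bits.sum())


def fingerprints_from_smiles(smiles: Mapping[str, str], n_bits: int = 2048, radius: int = 2) -> dict[str, Fingerprint]:
    """Hashed circular (Morgan/ECFP) fingerprints from SMILES strings.

    Requires rdkit; unparseable SMILES are skipped with a warning.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out: dict[str, Fingerprint] = {}
    for drug, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            warnings.warn(f"unparseable SMILES for {drug!r}; skipped")
            continue
        fp = gen.GetFingerprint(mol)
        out[drug] = Fingerprint(bits=np.array(fp, dtype=bool), source=smi)
    return out


def dice_similarity(a: Fingerprint | np.ndarray, b: Fingerprint | np.ndarray) -> float:
    """Dice coefficient 2c/(a+b) over ON-bit counts; two empty prints → 0."""
    ba = a.bits if isinstance(a, Fingerprint) else np.asarray(a).astype(bool)
    bb = b.bits if isinstance(b, Fingerprint) else np.asarray(b).astype(bool)
    if ba.size != bb.size:
        raise ValueError("fingerprint length mismatch")
    na, nb = int(ba.sum()), int(bb.sum())
    if na + nb == 0:
        warnings.warn("both fingerprints empty; Dice defined as 0")
        return 0.0
    c = int((ba & bb).sum())
    return 2.0 * c / (na + nb)


def pairwise_set_intersections(groups: Mapping[str, set], pairs: Iterable[tuple[str, str]]) -> dict[tuple[str, str], int]:
    """|A ∩ B| per drug pair; pairs with an unknown member are skipped."""
    out: dict[tuple[str, str], int] = {}
    for a, b in pairs:
        if a not in groups or b not in groups:
            warnings.warn(f"unknown drug in pair ({a}, {b}); skipped")
            continue
        out[(a, b)] = len(set(groups[a]) & set(groups[b]))
    return out


def secondary_targets(primary: set, signalling, order: int = 2) -> set:
    """Directed ≤ order-hop closure of the primary target set.

    ``signalling`` is a networkx.DiGraph (or any object with ``successors``).
    Targets absent from the network are kept but contribute no neighbours.
    """
    expanded = set(primary)
    frontier = set(primary)
    for _ in range(order):
        nxt = set()
        for node in frontier:
            if node in signalling:
                nxt.update(signalling.successors(node))
        nxt -= expanded
        expanded |= nxt
        frontier = nxt
    return expanded


def pathway_intersections(
    targets: Mapping[str, set],
    pathways: Mapping[str, set],
    pairs: Iterable[tuple[str, str]],
) -> dict[tuple[str, str], int]:
    """Shared-pathway counts per drug pair.

    A drug's pathway profile is every pathway hit by at least one of its
    targets; the pair statistic is the size of the profile intersection.
    """
    profile = {
        drug: {p for p, genes in pathways.items() if set(tset) & set(genes)}
        for drug, tset in targets.items()
    }
    return pairwise_set_intersections(profile, pairs)


def harmonic_similarity(P: Sequence[float], Q: Sequence[float]) -> float:
    """2 · Σ P_i·Q_i/(P_i+Q_i); genes with P_i + Q_i = 0 dropped (counted).

    For P = Q > 0 this reduces to Σ P_i.  Suited to signed (log-scale)
    expression values where a plain cosine would discard magnitude.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.size != Q.size:
        raise ValueError("vector length mismatch")
    denom = P + Q
    keep = denom != 0
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"{dropped} genes with P_i + Q_i = 0 dropped")
    if not keep.any():
        return float("nan")
    return float(2.0 * np.sum(P[keep] * Q[keep] / denom[keep]))


def jaccard_distance(P: Sequence[float], Q: Sequence[float], form: str = "standard") -> float:
    """Continuous Jaccard distance between expression vectors.

    standard (Tanimoto): 1 − ΣPQ/(ΣP² + ΣQ² − ΣPQ), zero self-distance.
    as_printed: 1 − ΣPQ/(ΣP² + ΣQ² + ΣPQ), whose self-distance is 2/3 for
    any nonzero vector; kept selectable for literal reproduction.
    """
    if form not in ("standard", "as_printed"):
        raise ValueError(f"unknown form: {form!r}")
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.size != Q.size:
        raise ValueError("vector length mismatch")
    pq = float(np.sum(P * Q))
    pp = float(np.sum(P * P))
    qq = float(np.sum(Q * Q))
    denom = pp + qq + pq if form == "as_printed" else pp + qq - pq
    if denom == 0:
        return float("nan")
    return 1.0 - pq / denom


def within_cluster_pairs(clusters: Mapping[int, Sequence[str]]) -> dict[int, list[tuple[str, str]]]:
    return {c: list(combinations(sorted(members), 2)) for c, members in clusters.items()}


def random_grouping_null(
    items: Sequence[str],
    metric: Callable[[str, str], float],
    group_sizes: Sequence[int],
    n_perm: int,
    seed: int,
    max_values: int | None = None,
) -> np.ndarray:
    """Pooled within-group metric values under random regrouping.

    Each permutation shuffles the items, cuts them into groups of the
    observed sizes and evaluates the metric over every within-group pair.
    Pairs where the metric is NaN are skipped and counted.  Identical seeds
    give identical null samples.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse null")
    rng = np.random.default_rng(seed)
    items = list(items)
    values: list[float] = []
    n_skipped = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(items))
        start = 0
        for size in group_sizes:
            group = [items[i] for i in perm[start:start + size]]
            start += size
            for a, b in combinations(group, 2):
                v = metric(a, b)
                if np.isnan(v):
                    n_skipped += 1
                    continue
                values.append(v)
        if max_values is not None and len(values) >= max_values:
            break
    if n_skipped:
        warnings.warn(f"{n_skipped} null pairs skipped (metric undefined)")
    out = np.asarray(values, dtype=float)
    return out[:max_values] if max_values is not None else out


@dataclass
class HomogeneityReport:
    """Cluster-vs-null comparison for one homogeneity metric."""

    metric: str
    within: dict[int, np.ndarray]
    null: np.ndarray
    kruskal_statistic: float
    kruskal_p: float
    kruskal_p_adjusted: float
    pairwise_wilcoxon: pd.DataFrame  # cluster, statistic, p, p_adjusted
    tie_warning: bool = False

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "group": f"cluster {c}",
                "n": len(v),
                "median": float(np.median(v)) if len(v) else np.nan,
                "mean": float(np.mean(v)) if len(v) else np.nan,
            }
            for c, v in sorted(self.within.items())
        ]
        rows.append({
            "group": "null",
            "n": len(self.null),
            "median": float(np.median(self.null)),
            "mean": float(np.mean(self.null)),
        })
        return pd.DataFrame(rows)


def compare_distributions(
    within: Mapping[int, Sequence[float]],
    null: Sequence[float],
    metric: str = "metric",
    alternative: str = "two-sided",
) -> HomogeneityReport:
    """Kruskal–Wallis across clusters + null, Wilcoxon rank-sum per cluster vs null.

    All p-values are Benjamini–Hochberg adjusted (KW jointly with the
    pairwise family).  Fully tied data yield p = 1 with a tie warning.
    """
    groups = {int(c): np.asarray(v, dtype=float) for c, v in within.items()}
    null = np.asarray(null, dtype=float)
    if any(len(v) < 3 for v in groups.values()) or len(null) < 3:
        raise ValueError("each group needs at least 3 values")
    all_vals = np.concatenate([*groups.values(), null])
    tie = bool(np.ptp(all_vals) == 0)
    if tie:
        warnings.warn("all values tied; p-values set to 1")
        kw_stat, kw_p = 0.0, 1.0
        praw = [1.0] * len(groups)
        stats_w = [0.5 * len(v) * len(null) for v in groups.values()]
    else:
        kw_stat, kw_p = stats.kruskal(*groups.values(), null)
        stats_w, praw = [], []
        for c, v in sorted(groups.items()):
            if np.ptp(np.concatenate([v, null])) == 0:
                s, p = 0.5 * len(v) * len(null), 1.0
            else:
                s, p = stats.mannwhitneyu(v, null, alternative=alternative)
            stats_w.append(float(s))
            praw.append(float(p))
    adjusted = stats.false_discovery_control([kw_p, *praw], method="bh")
    pw = pd.DataFrame({
        "cluster": sorted(groups),
        "statistic": stats_w,
        "p": praw,
        "p_adjusted": adjusted[1:],
    })
    return HomogeneityReport(
        metric=metric,
        within=groups,
        null=null,
        kruskal_statistic=float(kw_stat),
        kruskal_p=float(kw_p),
        kruskal_p_adjusted=float(adjusted[0]),
        pairwise_wilcoxon=pw,
        tie_warning=tie,
    )


def mutation_profile(
    mutations: pd.DataFrame,
    partition: Mapping[str, int],
    damage_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-cluster damaging-mutation frequencies with cross-cluster rank shifts.

    ``mutations`` holds columns sample_id, gene, damage_probability.  Only
    mutations with damage_probability strictly greater than the threshold
    count.  Frequency is the fraction of the cluster's samples carrying at
    least one damaging mutation of the gene; ranks are dense descending by
    frequency, and ``rank_shift`` is the rank difference relative to the
    first (lowest-labelled) cluster.
    """
    needed = {"sample_id", "gene", "damage_probability"}
    if not needed <= set(mutations.columns):
        raise ValueError(f"mutation table needs columns {sorted(needed)}")
    damaging = mutations[mutations["damage_probability"] > damage_threshold]
    clusters: dict[int, list[str]] = {}
    for sample, c in partition.items():
        clusters.setdefault(int(c), []).append(sample)
    genes = sorted(damaging["gene"].unique())
    frames = []
    for c, samples in sorted(clusters.items()):
        if not samples:
            continue
        sub = damaging[damaging["sample_id"].isin(samples)]
        carriers = sub.groupby("gene")["sample_id"].nunique()
        freq = pd.Series(0.0, index=genes, name="frequency")
        freq.loc[carriers.index] = carriers / len(samples)
        rank = freq.rank(ascending=False, method="dense")
        frames.append(pd.DataFrame({
            "cluster": c,
            "gene": genes,
            "frequency": freq.values,
            "rank": rank.values,
        }))
    if not frames:
        raise ValueError("no cluster has samples")
    out = pd.concat(frames, ignore_index=True)
    first = out["cluster"].min()
    base = out[out["cluster"] == first].set_index("gene")["rank"]
    out["rank_shift"] = out.apply(lambda r: r["rank"] - base.get(r["gene"], np.nan), axis=1)
    return out
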