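"""Synthetic drug-response cohorts with planted block structure.

Every pipeline stage can be exercised without external downloads: the
generator plants a drug-cluster × sample-cluster block structure in the
monotherapy viability curves (the signal that community detection must
recover), matching structure in the chemical/target/pathway annotations and
in the expression and mutation profiles (the signal that the homogeneity
statistics must detect), and a constant synergy offset on inter-cluster
combinations (the signal that the design comparison must detect).

All randomness flows from one integer seed; every generator derives an
independent substream from (seed, purpose), so each artefact can be
regenerated on its own and two runs with the same spec are identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .design import DesignSet
from .homogeneity import Fingerprint
from .synergy import CombinationMatrix

__all__ = [
    "CohortSpec",
    "Annotations",
    "cluster_labels",
    "generate_responses",
    "generate_annotations",
    "generate_combinations",
]

DEFAULT_DOSES = 10.0 * 10.0 ** (0.5 * np.arange(7))  # 7 half-log doses, 1000-fold


def _rng(seed: int, purpose: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(purpose.encode())])


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror the desk-scale study design: an 88 × 88 complete screen
    with two drug and two sample clusters, seven half-log doses spanning a
    1000-fold range, matched blocks sensitive (median viability 0.2) and
    crossed blocks resistant (0.8), and a +10 percentage-point synergy offset
    planted on inter-cluster combinations.
    """

    n_drugs: int = 88
    n_samples: int = 88
    n_drug_clusters: int = 2
    n_sample_clusters: int = 2
    block_potency: np.ndarray | None = None  # drug-cluster × sample-cluster medians
    noise_sd: float = 0.05
    missing_rate: float = 0.0
    dose_grid: np.ndarray = field(default_factory=lambda: DEFAULT_DOSES.copy())
    # chemistry / target / pathway planting
    n_bits: int = 2048
    fp_density: float = 0.08
    fingerprint_similarity_within: float = 0.85
    fingerprint_similarity_between: float = 0.30
    n_proteins: int = 200
    core_target_size: int = 8
    target_overlap_within: int = 5
    target_overlap_between: int = 1
    target_extra: int = 3
    n_pathways_per_cluster: int = 3
    n_random_pathways: int = 10
    # expression / mutation planting
    n_genes: int = 400
    n_signature_genes: int = 80
    expression_effect: float = 2.0
    expression_noise_sd: float = 1.0
    marker_freqs: tuple = (0.38, 0.30, 0.25, 0.20, 0.15)
    n_background_mut_genes: int = 20
    background_mut_rate: float = 0.1
    # combinations
    planted_delta: float = 10.0  # percentage points on inter-cluster pairs
    combo_noise_sd: float = 1.0  # percent
    seed: int = 0

    def __post_init__(self):
        if self.block_potency is None:
            bp = np.full((self.n_drug_clusters, self.n_sample_clusters), 0.8)
            for c in range(min(self.n_drug_clusters, self.n_sample_clusters)):
                bp[c, c] = 0.2
            self.block_potency = bp
        self.block_potency = np.asarray(self.block_potency, dtype=float)
        if self.block_potency.shape != (self.n_drug_clusters, self.n_sample_clusters):
            raise ValueError("block_potency shape must be n_drug_clusters × n_sample_clusters")
        if np.any((self.block_potency < 0) | (self.block_potency > 1.2)):
            raise ValueError("block median viabilities must lie in [0, 1.2]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.fingerprint_similarity_within <= self.fingerprint_similarity_between:
            raise ValueError("within-cluster fingerprint similarity must exceed between")
        if self.target_overlap_within <= self.target_overlap_between:
            raise ValueError("within-cluster target overlap must exceed between")
        if self.target_overlap_within > self.core_target_size:
            raise ValueError("target overlap exceeds core target set size")
        if self.n_drug_clusters * self.core_target_size > self.n_proteins:
            raise ValueError("protein universe too small for cluster cores")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.dose_grid = np.asarray(self.dose_grid, dtype=float)

    @property
    def drug_ids(self) -> list[str]:
        return [f"D{i:03d}" for i in range(self.n_drugs)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i:03d}" for i in range(self.n_samples)]


def cluster_labels(spec: CohortSpec) -> tuple[pd.Series, pd.Series]:
    """Ground-truth cluster assignment (round-robin over ids)."""
    drugs = pd.Series(
        [i % spec.n_drug_clusters for i in range(spec.n_drugs)],
        index=spec.drug_ids, name="cluster",
    )
    samples = pd.Series(
        [i % spec.n_sample_clusters for i in range(spec.n_samples)],
        index=spec.sample_ids, name="cluster",
    )
    return drugs, samples


def _curve_tables(spec: CohortSpec):
    """Per-pair 4PL parameters: (upper, lower, ec50, slope) matrices.

    Curves run from the untreated control plateau (viability 1) down to full
    kill (0); the EC50 is placed so the curve passes through the block-mean
    viability at the middle tested dose, making the 7-dose median equal the
    block mean exactly in the noiseless limit whatever the (jittered) slope.
    Block means are clipped into [0.02, 0.98] for the EC50 solve.
    """
    rng = _rng(spec.seed, "curves")
    slopes = rng.uniform(1.2, 1.8, size=(spec.n_drugs, spec.n_samples))
    dclu, sclu = cluster_labels(spec)
    m = spec.block_potency[dclu.to_numpy()[:, None], sclu.to_numpy()[None, :]]
    m = np.clip(m, 0.02, 0.98)
    upper = np.ones_like(m)
    lower = np.zeros_like(m)
    d_mid = float(np.exp(np.mean(np.log(spec.dose_grid))))  # geometric middle dose
    # solve 1/(1 + (d_mid/ec50)^s) = m  →  ec50 = d_mid / (1/m − 1)^(1/s)
    ec50 = d_mid / (1.0 / m - 1.0) ** (1.0 / slopes)
    return upper, lower, ec50, slopes


def _viability(dose, upper, lower, ec50, slope):
    return lower + (upper - lower) / (1.0 + (dose / ec50) ** slope)


def generate_responses(spec: CohortSpec):
    """Long response table + ground-truth labels.

    Returns ``(responses, truth)`` where responses has columns drug_id,
    sample_id, dose_nM, response and truth is a dict with "drug_clusters"
    and "sample_clusters" Series.  Cells are dropped entirely (all doses) at
    ``missing_rate``.
    """
    upper, lower, ec50, slopes = _curve_tables(spec)
    rng = _rng(spec.seed, "responses")
    noise = rng.normal(0.0, spec.noise_sd or 0.0,
                       size=(spec.n_drugs, spec.n_samples, spec.dose_grid.size))
    missing = _rng(spec.seed, "missing").random((spec.n_drugs, spec.n_samples)) < spec.missing_rate

    doses = spec.dose_grid
    records = []
    drug_ids, sample_ids = spec.drug_ids, spec.sample_ids
    for i in range(spec.n_drugs):
        for j in range(spec.n_samples):
            if missing[i, j]:
                continue
            y = _viability(doses, upper[i, j], lower[i, j], ec50[i, j], slopes[i, j])
            y = np.clip(y + noise[i, j], 0.0, 1.2)
            for d, v in zip(doses, y):
                records.append((drug_ids[i], sample_ids[j], d, v))
    responses = pd.DataFrame(records, columns=["drug_id", "sample_id", "dose_nM", "response"])
    dclu, sclu = cluster_labels(spec)
    return responses, {"drug_clusters": dclu, "sample_clusters": sclu}


@dataclass
class Annotations:
    """All prior-knowledge artefacts for a synthetic cohort."""

    fingerprints: dict[str, Fingerprint]
    targets: dict[str, set]
    signalling: nx.DiGraph
    pathways: dict[str, set]
    expression: pd.DataFrame  # genes × samples
    mutations: pd.DataFrame   # sample_id, gene, damage_probability


def generate_annotations(spec: CohortSpec) -> Annotations:
    """Cluster-templated chemistry, targets, pathways, expression, mutations."""
    dclu, sclu = cluster_labels(spec)

    # --- fingerprints: cluster prototypes blended from a global prototype ---
    rng = _rng(spec.seed, "fingerprints")
    global_proto = rng.random(spec.n_bits) < spec.fp_density
    protos = []
    for _ in range(spec.n_drug_clusters):
        fresh = rng.random(spec.n_bits) < spec.fp_density
        keep = rng.random(spec.n_bits) < spec.fingerprint_similarity_between
        protos.append(np.where(keep, global_proto, fresh))
    fingerprints = {}
    for drug, c in dclu.items():
        fresh = rng.random(spec.n_bits) < spec.fp_density
        keep = rng.random(spec.n_bits) < spec.fingerprint_similarity_within
        fingerprints[drug] = Fingerprint(bits=np.where(keep, protos[c], fresh))

    # --- targets over a protein universe with disjoint cluster cores ---
    rng = _rng(spec.seed, "targets")
    proteins = [f"P{i:03d}" for i in range(spec.n_proteins)]
    cores = [
        proteins[c * spec.core_target_size:(c + 1) * spec.core_target_size]
        for c in range(spec.n_drug_clusters)
    ]
    non_core = proteins[spec.n_drug_clusters * spec.core_target_size:]
    targets: dict[str, set] = {}
    for drug, c in dclu.items():
        own = rng.choice(cores[c], size=spec.target_overlap_within, replace=False)
        others = [p for cc, core in enumerate(cores) if cc != c for p in core]
        cross = rng.choice(others, size=min(spec.target_overlap_between, len(others)),
                           replace=False) if others else []
        extra = rng.choice(non_core, size=min(spec.target_extra, len(non_core)), replace=False)
        targets[drug] = set(own) | set(cross) | set(extra)

    # --- signalling network: sparse random directed graph over all proteins ---
    rng = _rng(spec.seed, "signalling")
    signalling = nx.DiGraph()
    signalling.add_nodes_from(proteins)
    for p in proteins:
        for q in rng.choice(proteins, size=3, replace=False):
            if q != p:
                signalling.add_edge(p, q, interaction="activates")

    # --- pathways: per-cluster pathways over the core + random decoys ---
    rng = _rng(spec.seed, "pathways")
    pathways: dict[str, set] = {}
    for c, core in enumerate(cores):
        for k in range(spec.n_pathways_per_cluster):
            size = max(2, len(core) // 2)
            members = set(rng.choice(core, size=size, replace=False))
            members |= set(rng.choice(non_core, size=4, replace=False))
            pathways[f"PW_C{c}_{k}"] = members
    for k in range(spec.n_random_pathways):
        pathways[f"PW_RND_{k}"] = set(rng.choice(proteins, size=15, replace=False))

    # --- expression: additive cluster shift on a signature gene block ---
    rng = _rng(spec.seed, "expression")
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    base = rng.uniform(1.0, 10.0, size=spec.n_genes)
    expr = np.empty((spec.n_genes, spec.n_samples))
    sig_per_cluster = max(1, spec.n_signature_genes // max(1, spec.n_sample_clusters))
    for j, (sample, c) in enumerate(sclu.items()):
        vals = base + rng.normal(0.0, spec.expression_noise_sd, size=spec.n_genes)
        lo = c * sig_per_cluster
        vals[lo:lo + sig_per_cluster] += spec.expression_effect
        expr[:, j] = np.clip(vals, 0.05, None)
    expression = pd.DataFrame(expr, index=genes, columns=spec.sample_ids)

    # --- mutations: cluster marker genes at planted frequencies + background ---
    rng = _rng(spec.seed, "mutations")
    records = []
    bg_genes = [f"MUT_BG{k:02d}" for k in range(spec.n_background_mut_genes)]
    for sample, c in sclu.items():
        for k, freq in enumerate(spec.marker_freqs):
            if rng.random() < freq:
                records.append((sample, f"MUT_C{c}_{k}", rng.uniform(0.6, 0.95)))
        for g in bg_genes:
            if rng.random() < spec.background_mut_rate:
                records.append((sample, g, rng.uniform(0.0, 1.0)))
    mutations = pd.DataFrame(records, columns=["sample_id", "gene", "damage_probability"])

    return Annotations(
        fingerprints=fingerprints, targets=targets, signalling=signalling,
        pathways=pathways, expression=expression, mutations=mutations,
    )


def true_inhibition_curve(spec: CohortSpec, drug_id: str, sample_id: str):
    """Ground-truth inhibition-fraction curve h(d) = clip(1 − viability, 0, 1)."""
    i = spec.drug_ids.index(drug_id)
    j = spec.sample_ids.index(sample_id)
    upper, lower, ec50, slopes = _curve_tables(spec)

    def h(dose):
        dose = np.asarray(dose, dtype=float)
        y = np.where(dose > 0,
                     _viability(np.where(dose > 0, dose, 1.0),
                                upper[i, j], lower[i, j], ec50[i, j], slopes[i, j]),
                     upper[i, j])
        return np.clip(1.0 - y, 0.0, 1.0)

    return h


def generate_combinations(
    spec: CohortSpec,
    design: DesignSet,
    sample_ids: Sequence[str] | None = None,
) -> tuple[list[CombinationMatrix], pd.DataFrame]:
    """Combination surfaces under Bliss independence of the true monotherapies.

    Positive (inter-cluster) pairs receive a constant ``planted_delta``
    percentage-point offset on the positive-dose grid; negative pairs none.
    Gaussian noise ``combo_noise_sd`` (%) is added to combination cells.
    Returns the matrices plus a truth table of planted offsets.
    """
    samples = list(sample_ids or design.cell_lines or spec.sample_ids[:1])
    rng = _rng(spec.seed, "combinations")
    doses = np.concatenate([[0.0], spec.dose_grid])
    matrices, truth_rows = [], []
    for group, pairs in (("positive", design.positive_pairs), ("negative", design.negative_pairs)):
        delta = spec.planted_delta if group == "positive" else 0.0
        for a, b in pairs:
            for s in samples:
                if a not in spec.drug_ids or b not in spec.drug_ids:
                    raise ValueError(f"pair ({a}, {b}) lacks monotherapy curves")
                ha, hb = true_inhibition_curve(spec, a, s), true_inhibition_curve(spec, b, s)
                y1 = ha(spec.dose_grid)
                y2 = hb(spec.dose_grid)
                grid = np.zeros((doses.size, doses.size))
                grid[1:, 0] = y1 * 100.0
                grid[0, 1:] = y2 * 100.0
                bliss = y1[:, None] + y2[None, :] - y1[:, None] * y2[None, :]
                combo = bliss * 100.0 + delta
                if spec.combo_noise_sd > 0:
                    combo = combo + rng.normal(0.0, spec.combo_noise_sd, size=combo.shape)
                grid[1:, 1:] = combo
                matrices.append(CombinationMatrix(
                    drug_a=a, drug_b=b, sample_id=s,
                    doses_a=doses.copy(), doses_b=doses.copy(), inhibition=grid,
                ))
                truth_rows.append({"drug_a": a, "drug_b": b, "sample_id": s,
                                   "group": group, "planted_delta": delta})
    return matrices, pd.DataFrame(truth_rows)
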