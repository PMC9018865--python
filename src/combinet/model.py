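"""Model-object interface over the bipartite screen pipeline.

:class:`BipartiteScreenModel` is constructed from a long drug-response table
(or directly from a median-viability matrix); :meth:`fit` runs the
measure → incidence → bipartite → projection → community chain and returns a
:class:`BipartiteScreenResults` carrying the networks, partitions,
diagnostics and a ``summary()`` table, with combination design hanging off
the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import community, design as design_mod, measures, network

__all__ = ["BipartiteScreenModel", "BipartiteScreenResults"]


class BipartiteScreenModel:
    """Weighted bipartite drug–sample network model of a monotherapy screen.

    Parameters
    ----------
    responses
        Long table with columns drug_id, sample_id, dose_nM, response
        (viability fraction); replicates are averaged per dose.
    weight_transform
        "reciprocal" (min–max of 1/median, the default) or "complement"
        (1 − min–max of the median); both decrease in median viability.

    Examples
    --------
    >>> model = BipartiteScreenModel(responses)
    >>> res = model.fit(seed=7)
    >>> res.drug_partition.n_clusters
    2
    """

    def __init__(self, responses: pd.DataFrame, weight_transform: str = "reciprocal"):
        if weight_transform not in ("reciprocal", "complement"):
            raise ValueError(f"unknown weight transform: {weight_transform!r}")
        needed = {"drug_id", "sample_id", "dose_nM", "response"}
        if not needed <= set(responses.columns):
            raise ValueError(f"responses must have columns {sorted(needed)}")
        self.responses = responses
        self.weight_transform = weight_transform
        self._medians: pd.DataFrame | None = None

    @classmethod
    def from_medians(cls, medians: pd.DataFrame, weight_transform: str = "reciprocal"):
        """Construct directly from a drug × sample median-viability matrix."""
        obj = cls.__new__(cls)
        obj.responses = None
        obj.weight_transform = weight_transform
        obj._medians = medians
        return obj

    @property
    def medians(self) -> pd.DataFrame:
        """Drug × sample median-viability matrix (NaN for untested cells)."""
        if self._medians is None:
            agg = measures.aggregate_replicates(self.responses)
            med = agg.groupby(["drug_id", "sample_id"])["response"].median().unstack()
            self._medians = med
        return self._medians

    def fit(self, algorithms=("fastgreedy",), seed: int | None = None) -> "BipartiteScreenResults":
        """Run the pipeline through community detection on both projections."""
        med = self.medians
        incidence = network.incidence_from_medians(med, transform=self.weight_transform)
        bipartite = network.build_bipartite(incidence)
        dsn = network.project(incidence, side="drugs")
        psn = network.project(incidence, side="samples")
        drug_part = community.best_partition(dsn, algorithms=algorithms, seed=seed)
        sample_part = community.best_partition(psn, algorithms=algorithms, seed=seed)
        return BipartiteScreenResults(
            model=self,
            incidence=incidence,
            bipartite=bipartite,
            dsn=dsn,
            psn=psn,
            drug_partition=drug_part,
            sample_partition=sample_part,
            removed=getattr(incidence, "removal_log", []),
        )


@dataclass
class BipartiteScreenResults:
    """Fitted networks and community structure of a bipartite screen model."""

    model: BipartiteScreenModel
    incidence: network.IncidenceMatrix
    bipartite: "object"
    dsn: network.SimilarityNetwork
    psn: network.SimilarityNetwork
    drug_partition: community.Partition
    sample_partition: community.Partition
    removed: list = field(default_factory=list)

    @property
    def drug_clusters(self) -> dict[int, list[str]]:
        return self.drug_partition.members()

    @property
    def sample_clusters(self) -> dict[int, list[str]]:
        return self.sample_partition.members()

    def drug_potency(self) -> pd.Series:
        """Median viability per drug across the retained samples (potency ranking key)."""
        frame = self.incidence.to_frame()
        med = self.model.medians
        return med.loc[frame.index, frame.columns].median(axis=1)

    def network_stats(self) -> pd.DataFrame:
        rows = []
        for name, net in (("DSN", self.dsn), ("PSN", self.psn)):
            st = network.network_stats(net)
            rows.append({
                "network": name,
                "nodes": net.graph.number_of_nodes(),
                "edges": net.graph.number_of_edges(),
                "heterogeneity": st.heterogeneity,
                "degree_centralization": st.degree_centralization,
                "mean_weighted_clustering": st.mean_weighted_clustering,
                "Q": (self.drug_partition if name == "DSN" else self.sample_partition).modularity,
                "n_clusters": (self.drug_partition if name == "DSN" else self.sample_partition).n_clusters,
            })
        return pd.DataFrame(rows)

    def design(self, k: int = 5, cell_lines=None) -> design_mod.DesignSet:
        """Top-k inter/intra-cluster combination design from the drug communities."""
        potency = self.drug_potency().to_dict()
        return design_mod.build_design(self.drug_clusters, potency, k=k, cell_lines=cell_lines)

    def plot_networks(self, axes=None):
        """Draw DSN and PSN with node size ∝ strength, coloured by community.

        Requires matplotlib; returns the two axes.
        """
        import matplotlib.pyplot as plt
        import networkx as nx

        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(11, 5))
        for ax, name, net, part in (
            (axes[0], "DSN", self.dsn, self.drug_partition),
            (axes[1], "PSN", self.psn, self.sample_partition),
        ):
            strengths = net.strengths()
            smax = max(strengths.values()) or 1.0
            pos = nx.spring_layout(net.graph, seed=0, weight="weight")
            nx.draw_networkx(
                net.graph, pos=pos, ax=ax, with_labels=False,
                node_size=[20 + 180 * strengths[v] / smax for v in net.graph.nodes],
                node_color=[part.assignment[v] for v in net.graph.nodes],
                cmap="tab10", edge_color="0.85", width=0.3,
            )
            ax.set_title(f"{name} (Q={part.modularity:.3f})")
            ax.set_axis_off()
        return axes

    def summary(self) -> str:
        n_d, n_s = len(self.incidence.drug_ids), len(self.incidence.sample_ids)
        stats = self.network_stats()
        lines = [
            "Bipartite screen model",
            "=" * 58,
            f"Incidence matrix      {n_d} drugs x {n_s} samples (complete)",
            f"Weight transform      {self.model.weight_transform}",
            f"Bipartite graph       {n_d + n_s} nodes, {n_d * n_s} edges",
            "",
            stats.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            "",
            f"Drug communities      {self.drug_partition.n_clusters} "
            f"(sizes {sorted(map(len, self.drug_clusters.values()), reverse=True)}, "
            f"Q={self.drug_partition.modularity:.4f}, {self.drug_partition.algorithm})",
            f"Sample communities    {self.sample_partition.n_clusters} "
            f"(sizes {sorted(map(len, self.sample_clusters.values()), reverse=True)}, "
            f"Q={self.sample_partition.modularity:.4f}, {self.sample_partition.algorithm})",
        ]
        return "\n".join(lines)
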