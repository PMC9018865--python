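"""Readers and writers for the plain-text formats the pipeline consumes.

All inputs are flat text: long response CSV, SMILES / fingerprint CSV,
two-column target TSV, SIF signalling edges, GMT pathway sets, genes ×
samples expression CSV, mutation CSV and combination CSV.  Networks round-
trip through GraphML or a weighted edge-list TSV with 6 significant digits.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .homogeneity import Fingerprint
from .network import SimilarityNetwork
from .synergy import CombinationMatrix

RESPONSE_COLUMNS = ["drug_id", "sample_id", "dose_nM", "response"]


class ParseError(ValueError):
    pass


def read_response_csv(path) -> pd.DataFrame:
    """Long response table; replicate column optional."""
    df = pd.read_csv(path)
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def write_measures_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_incidence_csv(incidence, path) -> None:
    incidence.to_frame().to_csv(path, index_label="drug_id")


def read_incidence_csv(path):
    from .network import IncidenceMatrix

    df = pd.read_csv(path, index_col=0)
    return IncidenceMatrix(
        drug_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        weights=df.to_numpy(),
    )


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path) -> nx.Graph:
    try:
        return nx.read_graphml(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_edgelist_tsv(net: SimilarityNetwork | nx.Graph, path) -> None:
    """source / target / weight TSV, weights at 6 significant digits."""
    g = net.graph if isinstance(net, SimilarityNetwork) else net
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, w in sorted(g.edges(data="weight")):
            fh.write(f"{u}\t{v}\t{float(w if w is not None else 1.0):.6g}\n")


def read_edgelist_tsv(path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != ["source", "target", "weight"]:
            raise ParseError(f"{path}:1: expected header source/target/weight")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields")
            try:
                g.add_edge(parts[0], parts[1], weight=float(parts[2]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
    if g.number_of_nodes() == 0:
        raise ParseError(f"{path}: empty network")
    return g


def write_partition_csv(partitions: Mapping[str, "object"], path) -> None:
    """Cluster assignment CSV over one or both similarity networks."""
    rows = []
    for side, part in partitions.items():
        for node, c in sorted(part.assignment.items()):
            rows.append({
                "node_id": node, "side": side, "cluster": c,
                "Q": part.modularity, "algorithm": part.algorithm,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_partition_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"node_id", "side", "cluster"}
    if not needed <= set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(needed - set(df.columns))}")
    return df


def read_smiles_csv(path) -> dict[str, str]:
    df = pd.read_csv(path)
    if not {"drug_id", "smiles"} <= set(df.columns):
        raise ParseError(f"{path}: needs drug_id,smiles columns")
    return dict(zip(df["drug_id"].astype(str), df["smiles"].astype(str)))


def read_fingerprint_csv(path) -> dict[str, Fingerprint]:
    """drug_id,bitstring rows; bitstring is e.g. '01001...'."""
    df = pd.read_csv(path, dtype=str)
    if not {"drug_id", "bitstring"} <= set(df.columns):
        raise ParseError(f"{path}: needs drug_id,bitstring columns")
    out = {}
    for _, row in df.iterrows():
        bits = np.frombuffer(row["bitstring"].encode(), dtype=np.uint8) - ord("0")
        if np.any(bits > 1):
            raise ParseError(f"{path}: non-binary bitstring for {row['drug_id']}")
        out[str(row["drug_id"])] = Fingerprint(bits=bits.astype(bool))
    return out


def write_fingerprint_csv(fps: Mapping[str, Fingerprint], path) -> None:
    rows = [
        {"drug_id": d, "bitstring": "".join("1" if b else "0" for b in fp.bits)}
        for d, fp in sorted(fps.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_targets_tsv(path) -> dict[str, set]:
    df = pd.read_csv(path, sep="\t", header=None, names=["drug_id", "protein_id"], dtype=str)
    out: dict[str, set] = {}
    for _, row in df.iterrows():
        out.setdefault(row["drug_id"], set()).add(row["protein_id"])
    return out


def write_targets_tsv(targets: Mapping[str, set], path) -> None:
    with open(path, "w") as fh:
        for drug in sorted(targets):
            for p in sorted(targets[drug]):
                fh.write(f"{drug}\t{p}\n")


def read_sif(path) -> nx.DiGraph:
    """SIF edge list: source <tab> interaction <tab> target."""
    g = nx.DiGraph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields")
            g.add_edge(parts[0], parts[2], interaction=parts[1])
    return g


def write_sif(g: nx.DiGraph, path) -> None:
    with open(path, "w") as fh:
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{data.get('interaction', 'interacts')}\t{v}\n")


def read_gmt(path) -> dict[str, set]:
    """GMT: name <tab> description <tab> member..."""
    out: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 fields")
            out[parts[0]] = set(parts[2:])
    return out


def write_gmt(pathways: Mapping[str, set], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(pathways):
            members = "\t".join(sorted(pathways[name]))
            fh.write(f"{name}\tsynthetic\t{members}\n")


def read_expression_csv(path) -> pd.DataFrame:
    """Genes × samples matrix with gene ids in the first column."""
    return pd.read_csv(path, index_col=0)


def read_mutation_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"sample_id", "gene", "damage_probability"}
    if not needed <= set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(needed - set(df.columns))}")
    return df


def read_combination_csv(path) -> list[CombinationMatrix]:
    """Long combination table → one matrix per (drug_a, drug_b, sample)."""
    df = pd.read_csv(path)
    needed = {"drug_a", "drug_b", "sample_id", "dose_a_nM", "dose_b_nM", "inhibition_pct"}
    if not needed <= set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(needed - set(df.columns))}")
    out = []
    for (a, b, s), grp in df.groupby(["drug_a", "drug_b", "sample_id"], sort=True):
        da = np.sort(grp["dose_a_nM"].unique())
        db = np.sort(grp["dose_b_nM"].unique())
        grid = (
            grp.pivot_table(index="dose_a_nM", columns="dose_b_nM", values="inhibition_pct")
            .reindex(index=da, columns=db)
        )
        if grid.isna().to_numpy().any():
            raise ParseError(f"{path}: incomplete dose grid for ({a}, {b}, {s})")
        out.append(CombinationMatrix(
            drug_a=str(a), drug_b=str(b), sample_id=str(s),
            doses_a=da, doses_b=db, inhibition=grid.to_numpy(),
        ))
    return out


def write_combination_csv(matrices, path) -> None:
    rows = []
    for m in matrices:
        for i, da in enumerate(m.doses_a):
            for j, db in enumerate(m.doses_b):
                rows.append({
                    "drug_a": m.drug_a, "drug_b": m.drug_b, "sample_id": m.sample_id,
                    "dose_a_nM": da, "dose_b_nM": db,
                    "inhibition_pct": m.inhibition[i, j],
                })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_synergy_csv(summaries, path) -> None:
    rows = []
    for s in summaries:
        for model, mean in s.means.items():
            rows.append({
                "drug_a": s.drug_a, "drug_b": s.drug_b, "sample_id": s.sample_id,
                "model": model, "mean_delta": mean,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_manifest(path, config: Mapping, seed, input_paths=()) -> None:
    """Run manifest: package version, seed, config hash and input hashes."""
    from . import __version__

    def _hash_file(p):
        h = hashlib.sha256()
        h.update(Path(p).read_bytes())
        return h.hexdigest()

    manifest = {
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {str(p): _hash_file(p) for p in input_paths},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
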