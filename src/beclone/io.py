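"""Reading and writing cohort tables and deconvoluted forests.

Cohort tables are plain TSV (see :class:`~beclone.model.Cohort` for the
dialect). A forest is archived as one Newick string per disjoint tree
(branch lengths are integer SNV counts, internal nodes are labelled) plus a
JSON sidecar carrying tip cell fractions, per-branch annotations, candidate
placements, and the origin count.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import pandas as pd

from .model import Clade, Cohort, LineageTip, PhylogenyForest, SchemaError


def read_cohort(snv_path, cn_path, meta_path) -> Cohort:
    """Load and validate the three cohort tables.

    Raises :class:`SchemaError`, :class:`ValidationError` or
    :class:`ReferentialError` on malformed input (see module docs).
    """
    meta = pd.read_csv(meta_path, sep="\t", dtype={"patient": str, "biopsy": str, "sample": str})
    snvs = pd.read_csv(snv_path, sep="\t", dtype={"patient": str, "chrom": str})
    cn = pd.read_csv(cn_path, sep="\t", dtype={"sample": str, "chrom": str})
    if "gd_corroborated" in meta.columns:
        meta["gd_corroborated"] = meta["gd_corroborated"].astype(bool)
    if "locus" in snvs.columns:
        snvs["locus"] = snvs["locus"].fillna("")
    return Cohort(meta=meta, snvs=snvs, cn=cn)


def write_cohort(cohort: Cohort, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "snvs": out / "snvs.tsv",
        "cn": out / "cn.tsv",
        "meta": out / "meta.tsv",
    }
    cohort.snvs.to_csv(paths["snvs"], sep="\t", index=False)
    cohort.cn.to_csv(paths["cn"], sep="\t", index=False)
    cohort.meta.to_csv(paths["meta"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Forest serialization
# ---------------------------------------------------------------------------

def forest_to_dict(forest: PhylogenyForest, origin_count: int | None = None,
                   placements: list[dict] | None = None) -> dict:
    forest.relabel()
    branches = {}
    tips = {}
    for node in forest.branches():
        if node.is_tip:
            tips[node.tip.label] = {
                "cell_fraction": node.tip.cell_fraction,
                "n_snvs": node.n_snvs,
                "private_snvs": node.private_snvs,
                "gd": node.gd,
                "partition_ids": list(node.partition_ids),
            }
        else:
            branches[node.label] = {
                "n_snvs": node.n_snvs,
                "gd": node.gd,
                "partition_ids": list(node.partition_ids),
            }
    return {
        "patient_id": forest.patient_id,
        "status": forest.status,
        "newick": [t.to_newick() for t in forest.trees],
        "origin_count": len(forest.trees) if origin_count is None else origin_count,
        "tips": tips,
        "branches": branches,
        "candidate_placements": placements or [],
    }


def write_forest(forest: PhylogenyForest, out_prefix, origin_count: int | None = None,
                 placements: list[dict] | None = None) -> dict:
    """Emit ``<prefix>.nwk`` (one tree per line) and ``<prefix>.forest.json``."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    payload = forest_to_dict(forest, origin_count=origin_count, placements=placements)
    nwk_path = prefix.with_suffix(".nwk")
    json_path = prefix.parent / (prefix.name + ".forest.json")
    nwk_path.write_text("\n".join(payload["newick"]) + "\n")
    json_path.write_text(json.dumps(payload, indent=1) + "\n")
    return {"newick": nwk_path, "json": json_path}


def forest_from_dict(payload: dict) -> PhylogenyForest:
    trees = []
    for nwk in payload["newick"]:
        dt = dendropy.Tree.get(data=nwk, schema="newick",
                               suppress_internal_node_taxa=True)
        trees.append(_from_dendropy(dt.seed_node, payload))
    forest = PhylogenyForest(payload["patient_id"], trees, status=payload.get("status", "resolved"))
    return forest


def read_forest(prefix) -> PhylogenyForest:
    prefix = Path(prefix)
    json_path = prefix.parent / (prefix.name + ".forest.json")
    payload = json.loads(json_path.read_text())
    return forest_from_dict(payload)


def _from_dendropy(dnode, payload: dict) -> Clade:
    if dnode.is_leaf():
        label = dnode.taxon.label.replace(" ", "_") if dnode.taxon else dnode.label
        info = payload["tips"].get(label)
        if info is None:
            raise SchemaError(f"tip {label!r} missing from sidecar")
        biopsy, _, idx = label.rpartition("-")
        node = Clade(n_snvs=info["n_snvs"],
                     tip=LineageTip(biopsy, int(idx), info["cell_fraction"]),
                     partition_ids=tuple(info.get("partition_ids", ())),
                     gd=info.get("gd", False),
                     private_snvs=info.get("private_snvs", 0))
        return node
    label = dnode.label
    info = payload["branches"].get(label, {}) if label else {}
    length = dnode.edge.length
    node = Clade(n_snvs=int(info.get("n_snvs", 0 if length is None else length)),
                 partition_ids=tuple(info.get("partition_ids", ())),
                 gd=info.get("gd", False), label=label or "")
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child, payload))
    return node
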