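"""Shared data model: cohort tables, copy-number context, and phylogeny forests.

A *cohort* bundles three tables: biopsy metadata (patient, biopsy letter,
time point, distance in cm above the gastroesophageal junction, outcome),
somatic SNVs with per-sample read counts, and allele-specific copy-number
segments. A patient's deconvoluted phylogeny is a *forest*: one or more
rooted trees whose tips are (biopsy, lineage) pairs carrying cell fractions
(CF), with branches weighted by the number of SNVs assigned to them.
Disjoint trees within a patient represent candidate independent origins of
the Barrett's segment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TIME_POINTS = ("TP1", "TP2", "TP3")
OUTCOMES = ("CO", "NCO")
SEVERITIES = ("MODIFIER", "LOW", "MODERATE", "HIGH")
PLOIDY_CLASSES = ("near_diploid", "near_tetraploid")

#: columns identifying one SNV in the wide SNV table
SNV_FIXED_COLS = ["patient", "chrom", "pos", "ref", "alt", "severity", "locus"]


class SchemaError(ValueError):
    """A required column is missing or has the wrong shape."""


class ValidationError(ValueError):
    """A record violates a type invariant (e.g. alt_reads > total_reads)."""


class ReferentialError(ValueError):
    """Cross-table references are inconsistent (unknown or duplicate ids)."""


@dataclass(frozen=True)
class BiopsyMeta:
    patient_id: str
    biopsy_id: str
    sample_id: str
    time_point: str
    gej_distance: float
    outcome: str

    def __post_init__(self) -> None:
        if self.time_point not in TIME_POINTS:
            raise ValidationError(f"bad time_point {self.time_point!r}")
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"bad outcome {self.outcome!r}")
        if self.gej_distance < 0:
            raise ValidationError("gej_distance must be >= 0")


@dataclass(frozen=True)
class SampleContext:
    """Per-sample ploidy assessment and external genome-doubling evidence."""

    sample_id: str
    ploidy_class: str = "near_diploid"
    gd_corroborated: bool = False

    def __post_init__(self) -> None:
        if self.ploidy_class not in PLOIDY_CLASSES:
            raise ValidationError(f"bad ploidy_class {self.ploidy_class!r}")
        if self.gd_corroborated and self.ploidy_class != "near_tetraploid":
            raise ValidationError("gd_corroborated requires near_tetraploid ploidy")

    @property
    def total_copies(self) -> int:
        return 4 if self.ploidy_class == "near_tetraploid" else 2


@dataclass(frozen=True)
class CopyNumberSegment:
    sample_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError("segment start > end")
        if self.minor_cn > self.major_cn:
            raise ValidationError("minor_cn > major_cn")
        if self.major_cn < 0 or self.minor_cn < 0:
            raise ValidationError("negative copy number")


class Cohort:
    """Validated bundle of metadata, SNV, and copy-number tables.

    Parameters
    ----------
    meta:
        One row per sample: ``patient, biopsy, sample, time_point, gej_cm,
        outcome, ploidy_class, gd_corroborated``.
    snvs:
        Wide table, one row per variant: ``patient, chrom, pos, ref, alt,
        severity, locus`` plus ``<sample>_alt``/``<sample>_tot`` column pairs.
    cn:
        ``sample, chrom, start, end, major, minor`` segments (1-based,
        inclusive, non-overlapping per sample).
    """

    META_COLS = [
        "patient", "biopsy", "sample", "time_point", "gej_cm",
        "outcome", "ploidy_class", "gd_corroborated",
    ]
    CN_COLS = ["sample", "chrom", "start", "end", "major", "minor"]

    def __init__(self, meta: pd.DataFrame, snvs, cn: pd.DataFrame):
        self.meta = meta.reset_index(drop=True)
        self.cn = cn.reset_index(drop=True)
        # SNVs are kept per patient (with only that patient's sample
        # columns) so large cohorts stay dense in memory; the on-disk
        # dialect is still one wide table.
        if isinstance(snvs, dict):
            self.snv_tables = {p: df for p, df in snvs.items()}
        else:
            if "patient" not in snvs.columns:
                raise SchemaError("snv table missing column 'patient'")
            self.snv_tables = {}
            by_sample = meta.groupby("patient")["sample"].apply(list) \
                if "patient" in meta.columns and "sample" in meta.columns \
                else None
            for p, sub in snvs.groupby("patient", sort=True):
                cols = list(SNV_FIXED_COLS)
                samples = sorted(by_sample.get(p, [])) if by_sample is not None \
                    else sorted({c[:-4] for c in sub.columns
                                 if c.endswith("_alt")})
                for s in samples:
                    for k in ("alt", "tot", "det"):
                        col = f"{s}_{k}"
                        if col in sub.columns:
                            cols.append(col)
                # unknown-sample columns with data are caught in validate()
                extras = [c for c in sub.columns
                          if c.endswith(("_alt", "_tot")) and c not in cols
                          and sub[c].notna().any()]
                self.snv_tables[str(p)] = sub[[c for c in cols if c in sub.columns]
                                              + extras]
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        for col in self.META_COLS:
            if col not in self.meta.columns:
                raise SchemaError(f"meta table missing column {col!r}")
        for col in self.CN_COLS:
            if col not in self.cn.columns:
                raise SchemaError(f"cn table missing column {col!r}")
        for df in self.snv_tables.values():
            for col in SNV_FIXED_COLS:
                if col not in df.columns:
                    raise SchemaError(f"snv table missing column {col!r}")

        dup = self.meta.duplicated(subset=["patient", "biopsy"])
        if dup.any():
            rows = self.meta.loc[dup, ["patient", "biopsy"]].iloc[0]
            raise ReferentialError(
                f"duplicate biopsy_id {rows['biopsy']!r} in patient {rows['patient']!r}"
            )
        if self.meta["sample"].duplicated().any():
            raise ReferentialError("duplicate sample_id in metadata")
        bad_tp = ~self.meta["time_point"].isin(TIME_POINTS)
        if bad_tp.any():
            raise ValidationError(f"unknown time_point {self.meta.loc[bad_tp, 'time_point'].iloc[0]!r}")
        tp3_co = (self.meta["time_point"] == "TP3") & (self.meta["outcome"] == "CO")
        if tp3_co.any():
            raise ValidationError("TP3 samples only occur in NCO patients")
        if (self.meta["gej_cm"] < 0).any():
            raise ValidationError("gej_cm must be >= 0")

        known = set(self.meta["sample"])
        cn_unknown = set(self.cn["sample"]) - known
        if cn_unknown:
            raise ReferentialError(f"cn table sample {sorted(cn_unknown)[0]!r} not in metadata")

        for p, df in self.snv_tables.items():
            for s in self.sample_columns(p):
                if s not in known:
                    raise ReferentialError(f"SNV table sample {s!r} not in metadata")
                alt = df[f"{s}_alt"].to_numpy(dtype=float)
                tot = df[f"{s}_tot"].to_numpy(dtype=float)
                bad = np.nan_to_num(alt) > np.nan_to_num(tot)
                if bad.any():
                    idx = df.index[int(np.flatnonzero(bad)[0])]
                    raise ValidationError(
                        f"alt_reads > total_reads for sample {s!r} at row {idx}"
                    )
            bad_sev = ~df["severity"].isin(SEVERITIES)
            if bad_sev.any():
                raise ValidationError(
                    f"unknown severity {df.loc[bad_sev, 'severity'].iloc[0]!r}"
                )

    # -- accessors -------------------------------------------------------

    def sample_columns(self, patient: str) -> list[str]:
        """Sample ids with read-count column pairs in a patient's SNV table."""
        df = self.snv_tables[patient]
        alts = {c[:-4] for c in df.columns if c.endswith("_alt")}
        tots = {c[:-4] for c in df.columns if c.endswith("_tot")}
        return sorted(alts & tots)

    @property
    def snvs(self) -> pd.DataFrame:
        """All patients' SNVs as one wide table (the on-disk layout)."""
        return pd.concat(
            [self.snv_tables[p] for p in sorted(self.snv_tables)],
            ignore_index=True, sort=False)

    @property
    def patients(self) -> list[str]:
        return sorted(self.meta["patient"].unique())

    def samples_of(self, patient: str) -> list[str]:
        sub = self.meta[self.meta["patient"] == patient]
        return sorted(sub["sample"])

    def meta_of(self, sample: str) -> BiopsyMeta:
        row = self.meta.set_index("sample").loc[sample]
        return BiopsyMeta(
            patient_id=row["patient"], biopsy_id=row["biopsy"], sample_id=sample,
            time_point=row["time_point"], gej_distance=float(row["gej_cm"]),
            outcome=row["outcome"],
        )

    def context_of(self, sample: str) -> SampleContext:
        row = self.meta.set_index("sample").loc[sample]
        return SampleContext(
            sample_id=sample, ploidy_class=row["ploidy_class"],
            gd_corroborated=bool(row["gd_corroborated"]),
        )

    def patient_snvs(self, patient: str) -> pd.DataFrame:
        return self.snv_tables[patient].reset_index(drop=True)

    def cn_of(self, sample: str) -> pd.DataFrame:
        return self.cn[self.cn["sample"] == sample].reset_index(drop=True)

    def equals(self, other: "Cohort") -> bool:
        def norm(df, keys):
            return df.sort_values(keys).reset_index(drop=True)

        try:
            pd.testing.assert_frame_equal(
                norm(self.meta, ["patient", "biopsy"]),
                norm(other.meta, ["patient", "biopsy"]), check_dtype=False)
            if set(self.snv_tables) != set(other.snv_tables):
                return False
            for p in self.snv_tables:
                pd.testing.assert_frame_equal(
                    norm(self.patient_snvs(p), ["chrom", "pos"]),
                    norm(other.patient_snvs(p), ["chrom", "pos"]),
                    check_dtype=False, check_like=True)
            pd.testing.assert_frame_equal(
                norm(self.cn, ["sample", "chrom", "start"]),
                norm(other.cn, ["sample", "chrom", "start"]),
                check_dtype=False)
        except AssertionError:
            return False
        return True


# ---------------------------------------------------------------------------
# Phylogeny forest
# ---------------------------------------------------------------------------

@dataclass
class LineageTip:
    """One deconvoluted lineage observed in one biopsy.

    ``lineage_index`` distinguishes multiple lineages in the same biopsy
    (tip label ``<biopsy>-<index>``); ``cell_fraction`` is the proportion of
    the biopsy's cells assigned to the lineage at its divergence from the
    rest of the phylogeny.
    """

    biopsy_id: str
    lineage_index: int
    cell_fraction: float | None = None

    @property
    def label(self) -> str:
        return f"{self.biopsy_id}-{self.lineage_index}"


class Clade:
    """A node of one tree; the branch *above* the node carries SNVs.

    ``n_snvs`` counts multi-sample SNVs assigned to the branch;
    ``private_snvs`` (tips only) counts the lineage's private SNVs, which
    support the pendant branch but are never placed by the assignment
    algorithm. Resampling weights use their sum.
    """

    __slots__ = ("children", "parent", "n_snvs", "private_snvs",
                 "partition_ids", "gd", "tip", "label")

    def __init__(self, n_snvs: int = 0, tip: LineageTip | None = None,
                 partition_ids: tuple = (), gd: bool = False, label: str = "",
                 private_snvs: int = 0):
        self.children: list[Clade] = []
        self.parent: Clade | None = None
        self.n_snvs = int(n_snvs)
        self.private_snvs = int(private_snvs)
        self.partition_ids = tuple(partition_ids)
        self.gd = bool(gd)
        self.tip = tip
        self.label = label

    @property
    def length(self) -> int:
        """Total SNV support of the branch (assigned plus private)."""
        return self.n_snvs + self.private_snvs

    def add_child(self, child: "Clade") -> "Clade":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return self.tip is not None

    def walk(self):
        """Preorder traversal of the subtree rooted here."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list["Clade"]:
        return [n for n in self.walk() if n.is_tip]

    def biopsies(self) -> frozenset:
        return frozenset(t.tip.biopsy_id for t in self.tips())

    def ancestors(self):
        node = self.parent
        while node is not None:
            yield node
            node = node.parent

    def to_newick(self) -> str:
        def render(node: Clade) -> str:
            if node.is_tip:
                return f"{node.tip.label}:{node.length}"
            inner = ",".join(render(c) for c in node.children)
            lab = node.label or ""
            return f"({inner}){lab}:{node.n_snvs}"

        return render(self) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Clade {self.label or '?'} len={self.n_snvs} tips={sorted(self.biopsies())}>"


class PhylogenyForest:
    """A patient's deconvoluted lineages: one or more rooted trees.

    ``status`` is ``"resolved"`` or ``"unresolvable"`` (the latter mirrors
    patients whose partition sets admit no tree and are excluded from all
    downstream statistics).
    """

    def __init__(self, patient_id: str, trees: list[Clade], status: str = "resolved"):
        self.patient_id = patient_id
        self.trees = trees
        self.status = status
        self.relabel()

    def relabel(self) -> None:
        """Assign stable preorder labels T<i>.<j> to internal nodes."""
        for i, tree in enumerate(self.trees):
            for j, node in enumerate(tree.walk()):
                if not node.is_tip:
                    node.label = f"T{i}.{j}"

    # -- traversal -------------------------------------------------------

    def tips(self) -> list[Clade]:
        return [t for tree in self.trees for t in tree.tips()]

    def branches(self) -> list[Clade]:
        """All nodes (each node stands for the branch above it)."""
        return [n for tree in self.trees for n in tree.walk()]

    def tips_in(self, biopsy_id: str) -> list[Clade]:
        return [t for t in self.tips() if t.tip.biopsy_id == biopsy_id]

    def biopsy_ids(self) -> frozenset:
        return frozenset(t.tip.biopsy_id for t in self.tips())

    def node_by_label(self, label: str) -> Clade:
        for n in self.branches():
            if n.is_tip and n.tip.label == label:
                return n
            if not n.is_tip and n.label == label:
                return n
        raise KeyError(label)

    def subclonal_biopsies(self) -> set:
        """Biopsies represented by two or more lineages."""
        counts: dict[str, int] = {}
        for t in self.tips():
            counts[t.tip.biopsy_id] = counts.get(t.tip.biopsy_id, 0) + 1
        return {b for b, c in counts.items() if c >= 2}

    # -- comparison ------------------------------------------------------

    def clade_sets(self) -> set[frozenset]:
        """Tip-label sets of every internal edge plus every tree (for RF)."""
        out: set[frozenset] = set()
        for tree in self.trees:
            for node in tree.walk():
                labels = frozenset(t.tip.label for t in node.tips())
                if len(labels) >= 2:
                    out.add(labels)
        return out

    def rf_distance(self, other: "PhylogenyForest") -> int:
        """Symmetric difference of nontrivial clades over matched tip labels."""
        return len(self.clade_sets() ^ other.clade_sets())

    def equals(self, other: "PhylogenyForest") -> bool:
        if self.patient_id != other.patient_id or self.status != other.status:
            return False
        if len(self.trees) != len(other.trees):
            return False

        def key(node: Clade) -> str:
            if node.is_tip:
                cf = node.tip.cell_fraction
                return (f"L[{node.tip.label}|{node.n_snvs}|{node.private_snvs}|"
                        f"{-1 if cf is None else round(cf, 6)}|{node.gd}]")
            inner = ",".join(sorted(key(c) for c in node.children))
            return f"({inner})|{node.n_snvs}|{node.gd}"

        return sorted(key(t) for t in self.trees) == sorted(key(t) for t in other.trees)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<PhylogenyForest {self.patient_id} trees={len(self.trees)} "
                f"tips={len(self.tips())} status={self.status}>")


def new_tip(biopsy_id: str, lineage_index: int, cf: float | None = None,
            n_snvs: int = 0) -> Clade:
    return Clade(n_snvs=n_snvs, tip=LineageTip(biopsy_id, lineage_index, cf))
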