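"""Tabular containers and readers/writers for every on-disk format touched.

All tables are UTF-8, tab-delimited with a header row: expression matrices
(rows = features, columns = ``condition_time_replicate`` sample ids),
differential-expression tables, strain tolerance tables, multi-layer edge
lists, GMT pathway files, and FASTA transcripts.  Also hosts the two small
input-level filters: the lncRNA candidate filter (length / ORF / expression)
and the phenotype-specific differentially-abundant-metabolite rule.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .network import EDGE_COLUMNS, MultiLayerNetwork, merge_layers

DE_STATUSES = ("up", "down", "ns")


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


# ---------------------------------------------------------------------------
# ExpressionSeries
# ---------------------------------------------------------------------------

_SAMPLE_RE = re.compile(r"^(?P<cond>control|treatment)_(?P<time>[0-9.]+)_(?P<rep>\d+)$")


@dataclass
class ExpressionSeries:
    """log2 expression, features x samples, with condition/time/replicate labels.

    ``values`` is indexed by feature id; ``samples`` is indexed by sample id
    with columns ``condition`` (control/treatment), ``time`` (hours, float)
    and ``replicate`` (int).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise FormatError("sample annotations do not match value columns")
        if self.samples.index.duplicated().any():
            raise FormatError("duplicated sample ids")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicated feature ids: {dups[:5]}")
        if self.samples[["condition", "time"]].isna().any().any():
            raise FormatError("missing condition/time annotation")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def time_points(self) -> list[float]:
        return sorted(set(self.samples["time"]))

    def condition_means(self, condition: str) -> pd.Series:
        cols = self.samples.index[self.samples["condition"] == condition]
        if not len(cols):
            raise ValueError(f"no samples for condition {condition!r}")
        return self.values[cols].mean(axis=1)

    def timecourse(self, condition: str) -> pd.DataFrame:
        """Feature x time matrix of replicate means under one condition."""
        sub = self.samples[self.samples["condition"] == condition]
        if not len(sub):
            raise ValueError(f"no samples for condition {condition!r}")
        out = {}
        for t in sorted(set(sub["time"])):
            cols = sub.index[sub["time"] == t]
            out[t] = self.values[cols].mean(axis=1)
        return pd.DataFrame(out)


def sample_id(condition: str, time: float, replicate: int) -> str:
    t = int(time) if float(time).is_integer() else time
    return f"{condition}_{t}_{replicate}"


def write_expression(expr: ExpressionSeries, path) -> None:
    df = expr.values.copy()
    df.index.name = "feature"
    df.to_csv(path, sep="\t")


def read_expression(path) -> ExpressionSeries:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    ann = {}
    for i, col in enumerate(df.columns):
        m = _SAMPLE_RE.match(col)
        if not m:
            raise FormatError(f"{path}: column {i + 2}: bad sample id {col!r} "
                              "(expected condition_time_replicate)")
        ann[col] = (m["cond"], float(m["time"]), int(m["rep"]))
    samples = pd.DataFrame.from_dict(ann, orient="index",
                                     columns=["condition", "time", "replicate"])
    return ExpressionSeries(df, samples)


# ---------------------------------------------------------------------------
# DETable
# ---------------------------------------------------------------------------

@dataclass
class DETable:
    """Differential-expression calls: id, log2FC, adjusted p, status.

    ``status`` is forced to ``ns`` wherever ``padj`` exceeds ``alpha``
    (default 0.05).
    """

    table: pd.DataFrame
    alpha: float = 0.05

    def __post_init__(self) -> None:
        t = self.table
        required = {"id", "log2FC", "padj", "status"}
        if missing := required - set(t.columns):
            raise FormatError(f"DE table missing columns {sorted(missing)}")
        if t["id"].duplicated().any():
            raise FormatError("duplicated ids in DE table")
        if not set(t["status"]).issubset(DE_STATUSES):
            raise FormatError(f"bad status values: {set(t['status']) - set(DE_STATUSES)}")
        if ((t["padj"] < 0) | (t["padj"] > 1)).any():
            raise FormatError("padj must lie in [0, 1]")
        t.loc[t["padj"] > self.alpha, "status"] = "ns"
        self.table = t.reset_index(drop=True)

    def status_of(self, feature: str) -> str:
        row = self.table.loc[self.table["id"] == feature, "status"]
        return row.iloc[0] if len(row) else "ns"

    def significant(self, status: str | None = None) -> list[str]:
        t = self.table
        if status is None:
            return t.loc[t["status"] != "ns", "id"].tolist()
        return t.loc[t["status"] == status, "id"].tolist()


def write_de(de: DETable, path) -> None:
    de.table.to_csv(path, sep="\t", index=False)


def read_de(path, alpha: float = 0.05) -> DETable:
    return DETable(pd.read_csv(path, sep="\t"), alpha=alpha)


# ---------------------------------------------------------------------------
# ToleranceTable
# ---------------------------------------------------------------------------

@dataclass
class ToleranceTable:
    """Per-strain maximum tolerated ethanol concentration (% v/v)."""

    table: pd.DataFrame  # columns: strain, tolerance[, phenotype]

    def __post_init__(self) -> None:
        t = self.table
        if missing := {"strain", "tolerance"} - set(t.columns):
            raise FormatError(f"tolerance table missing columns {sorted(missing)}")
        if t["strain"].duplicated().any():
            raise FormatError("duplicated strain names")
        if ((t["tolerance"] <= 0) | (t["tolerance"] > 100)).any():
            raise FormatError("tolerances must lie in (0, 100]")
        self.table = t.reset_index(drop=True)

    @property
    def strains(self) -> list[str]:
        return self.table["strain"].tolist()

    def as_series(self) -> pd.Series:
        return self.table.set_index("strain")["tolerance"]


def read_tolerance(path) -> ToleranceTable:
    return ToleranceTable(pd.read_csv(path, sep="\t"))


def write_tolerance(tol: ToleranceTable, path) -> None:
    tol.table.to_csv(path, sep="\t", index=False)


def bundled_tolerance_table() -> ToleranceTable:
    """The six sequenced strains with their printed maximum EtOH tolerances."""
    return read_tolerance(Path(__file__).parent / "data" / "strain_tolerance.tsv")


# ---------------------------------------------------------------------------
# Edge lists and GMT
# ---------------------------------------------------------------------------

def read_edges(path) -> MultiLayerNetwork:
    df = pd.read_csv(path, sep="\t")
    if missing := {"source", "target", "layer"} - set(df.columns):
        raise FormatError(f"edge table missing columns {sorted(missing)}")
    for col in ("sign", "probability", "directed"):
        if col not in df.columns:
            df[col] = np.nan
    df["directed"] = df["layer"].eq("grn") if df["directed"].isna().all() else df["directed"]
    kinds = None
    if "source_kind" in df.columns and "target_kind" in df.columns:
        kinds = {}
        for row in df.itertuples(index=False):
            kinds[row.source] = row.source_kind
            kinds[row.target] = row.target_kind
    return merge_layers([df[EDGE_COLUMNS]], node_kinds=kinds)


def write_edges(net: MultiLayerNetwork, path) -> None:
    df = net.edges.copy()
    df["source_kind"] = df["source"].map(net.node_kinds)
    df["target_kind"] = df["target"].map(net.node_kinds)
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, set[str]]:
    """GMT pathway file: name <tab> description <tab> member*."""
    pathways: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected name<TAB>description<TAB>members")
            name = parts[0]
            if name in pathways:
                raise FormatError(f"{path}:{lineno}: duplicated pathway {name!r}")
            pathways[name] = set(parts[2:]) - {""}
    return pathways


def write_gmt(pathways: Mapping[str, Iterable[str]], path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in pathways:
            members = "\t".join(sorted(pathways[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


# ---------------------------------------------------------------------------
# Transcripts and the lncRNA candidate filter
# ---------------------------------------------------------------------------

@dataclass
class TranscriptRecord:
    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def longest_orf(self) -> int:
        """Longest ATG->stop open reading frame, in codons, on either strand."""
        return longest_orf_codons(self.sequence)


_STOPS = {"TAA", "TAG", "TGA"}


def longest_orf_codons(sequence: str) -> int:
    """Length in codons (ATG included, stop excluded) of the longest ORF.

    Scans all three frames on both strands under the standard genetic code.
    An ORF requires an in-frame stop codon downstream of the ATG.
    """
    best = 0
    seq = sequence.upper().replace("U", "T")
    for strand in (seq, str(Seq(seq).reverse_complement())):
        for frame in range(3):
            codons = [strand[i:i + 3] for i in range(frame, len(strand) - 2, 3)]
            start = None
            for i, codon in enumerate(codons):
                if codon == "ATG" and start is None:
                    start = i
                elif codon in _STOPS and start is not None:
                    best = max(best, i - start)
                    start = None
    return best


def read_transcripts(path) -> list[TranscriptRecord]:
    records = [TranscriptRecord(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        raise FormatError("duplicated transcript ids in FASTA")
    return records


def filter_lncrna_candidates(transcripts: Sequence[TranscriptRecord],
                             coding_expression_median: float,
                             expression: ExpressionSeries,
                             min_len: int = 200,
                             max_orf: int = 100) -> list[str]:
    """Apply the three defining lncRNA filters and return accepted ids.

    A transcript passes iff it is at least ``min_len`` nt long, its longest
    ORF is shorter than ``max_orf`` codons (lncRNAs lack substantial ORFs),
    and its mean expression lies below the coding-gene median (lncRNAs are
    expressed below coding genes).  Transcripts missing from the expression
    table are excluded and reported via the returned ``missing`` attribute
    on the error, not silently dropped.
    """
    mean_expr = expression.values.mean(axis=1)
    accepted = []
    for tr in transcripts:
        if tr.id not in mean_expr.index:
            continue  # absent from expression: excluded
        if (tr.length >= min_len
                and tr.longest_orf < max_orf
                and mean_expr[tr.id] < coding_expression_median):
            accepted.append(tr.id)
    return accepted


# ---------------------------------------------------------------------------
# Phenotype-specific differentially abundant metabolites
# ---------------------------------------------------------------------------

def phenotype_specific_dams(dam_tables: Mapping[str, pd.DataFrame],
                            phenotype_map: Mapping[str, str],
                            min_strains: int = 2) -> dict[str, set[str]]:
    """Metabolites differentially abundant, same direction, in >=2 strains of a phenotype.

    ``dam_tables`` maps strain -> DataFrame with columns ``id`` and
    ``direction`` (up/down).  Returns phenotype -> metabolite set.
    """
    phenos: dict[str, list[str]] = {}
    for strain, pheno in phenotype_map.items():
        phenos.setdefault(pheno, []).append(strain)
    for pheno, strains in phenos.items():
        if len(strains) < min_strains:
            raise ValueError(f"phenotype {pheno!r} has fewer than {min_strains} strains")

    out: dict[str, set[str]] = {p: set() for p in phenos}
    for pheno, strains in phenos.items():
        counts: dict[tuple[str, str], int] = {}
        for strain in strains:
            t = dam_tables.get(strain)
            if t is None:
                continue
            for row in t.itertuples(index=False):
                key = (row.id, row.direction)
                counts[key] = counts.get(key, 0) + 1
        out[pheno] = {m for (m, _d), c in counts.items() if c >= min_strains}
    return out
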