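"""Shared domain types, thresholds, file I/O and the taxonomy-consensus rule.

Coordinates follow the GFF3 convention (1-based, inclusive).  Proteins are
uppercased on ingest; ``U`` (selenocysteine) and ``X`` are tolerated residues
but ``X`` never matches a motif letter downstream.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("genopotential")

#: residues accepted in ingested protein sequences
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXU*")

#: default bit-score cutoff applied when no per-profile cutoffs are supplied
DEFAULT_BIT_SCORE_CUTOFF = 50.0

#: default rank names used when lineages are parsed from ';'-separated strings
DEFAULT_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


class MarkerSetError(ValueError):
    """Raised for an empty or malformed single-copy marker set."""


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

@dataclass
class Thresholds:
    """Every numeric decision boundary used by the pipeline, in one place.

    mhc_min_motifs
        CXXCH motifs needed to label a protein a multiheme cytochrome.
    iron_min_mhcs
        MHC proteins needed to predict a genome as an iron reducer.
    hq_min_completeness / hq_max_contamination
        Per cent bounds for a high-quality draft genome (strict: >70, <10).
    gap_col_max_frac
        Alignment columns with a gap fraction above this are removed.
    seq_min_aligned_frac
        Concatenated sequences below this non-gap fraction are dropped.
    tree_min_positions
        Non-gap columns required for a taxon to be tree-eligible.
    rare_abundance_frac
        Mean relative abundance below which an organism counts as rare
        (the 0.1 % row filter of the profile matrix).
    cooccur_ratio
        Fold-ratio bound for the optional abundance-correlation screen.
    operon_window
        Genes examined downstream of a catalytic hydrogenase subunit.
    derep_identity / derep_aligned_frac
        Nucleotide identity and aligned-fraction bounds for dereplication.
    rps3_cluster_identity
        Amino-acid identity for collapsing rpS3 marker sequences.
    """

    mhc_min_motifs: int = 10
    iron_min_mhcs: int = 4
    hq_min_completeness: float = 70.0
    hq_max_contamination: float = 10.0
    gap_col_max_frac: float = 0.90
    seq_min_aligned_frac: float = 0.50
    tree_min_positions: int = 450
    rare_abundance_frac: float = 0.001
    cooccur_ratio: float = 10.0
    operon_window: int = 3
    derep_identity: float = 0.98
    derep_aligned_frac: float = 0.50
    rps3_cluster_identity: float = 0.99

    def __post_init__(self) -> None:
        for name in ("mhc_min_motifs", "iron_min_mhcs", "tree_min_positions",
                     "operon_window"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("gap_col_max_frac", "seq_min_aligned_frac",
                     "rare_abundance_frac", "derep_identity",
                     "derep_aligned_frac", "rps3_cluster_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("hq_min_completeness", "hq_max_contamination"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.cooccur_ratio < 1:
            raise ValueError("cooccur_ratio must be >= 1")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def with_overrides(self, **overrides) -> "Thresholds":
        return replace(self, **overrides)

    @classmethod
    def from_json(cls, path) -> "Thresholds":
        """Build thresholds from a JSON override file (missing keys default)."""
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass
class Scaffold:
    scaffold_id: str
    length_bp: int
    depth: dict = field(default_factory=dict)  # sample_id -> mean read depth

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"scaffold {self.scaffold_id}: length_bp < 1")
        for sample, d in self.depth.items():
            if not (d >= 0):
                raise ValueError(
                    f"scaffold {self.scaffold_id}: bad depth {d!r} in {sample}")


@dataclass
class GeneCall:
    """One predicted protein-coding gene on a scaffold.

    ``ordinal`` is the strand-agnostic position of the gene among the genes
    of its scaffold, assigned by ascending start coordinate; "downstream"
    then means increasing ordinal on the + strand and decreasing on the −.
    """

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    ordinal: int = -1
    protein: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass
class GenomeBin:
    bin_id: str
    scaffold_ids: set
    domain: str = "unknown"
    taxonomy_evidence: tuple = (None, None, None)
    consensus_lineage: Optional["Lineage"] = None
    completeness: Optional[float] = None
    contamination: Optional[float] = None
    is_high_quality: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.scaffold_ids:
            raise ValueError(f"bin {self.bin_id}: empty scaffold set")


@dataclass(frozen=True)
class ProfileHit:
    gene_id: str
    profile: str
    bit_score: float
    e_value: float = 0.0

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")


@dataclass(frozen=True)
class Lineage:
    """An ordered lineage, coarse to fine, as (rank_name, taxon_name) pairs."""

    ranks: tuple

    def __post_init__(self) -> None:
        for rank, name in self.ranks:
            if not name:
                raise ValueError("empty taxon name in lineage")

    @classmethod
    def from_string(cls, text: str, rank_names: Sequence[str] = DEFAULT_RANKS
                    ) -> "Lineage":
        names = [t.strip() for t in text.split(";") if t.strip()]
        ranks = tuple(
            (rank_names[i] if i < len(rank_names) else f"rank{i}", n)
            for i, n in enumerate(names))
        return cls(ranks)

    def names(self) -> tuple:
        return tuple(name for _, name in self.ranks)

    def __str__(self) -> str:
        return ";".join(self.names())


UNASSIGNED = Lineage((("unranked", "unassigned"),))


def consensus_taxonomy(l16s: Optional[Lineage] = None,
                       lrib: Optional[Lineage] = None,
                       lvote: Optional[Lineage] = None) -> Lineage:
    """Consensus lineage: the most specific level on which all methods agree.

    Absent lines of evidence are skipped (with a warning when fewer than
    three are present); an empty shared prefix yields ``unassigned``.
    Order-invariant in its arguments and idempotent on its own output.
    """
    present = [l for l in (l16s, lrib, lvote) if l is not None]
    if not present:
        raise ValueError("no taxonomy evidence")
    if len(present) < 3:
        logger.warning("taxonomy consensus over %d of 3 evidence lines",
                       len(present))
    shared = []
    for level in zip(*(l.ranks for l in present)):
        names = {name for _, name in level}
        if len(names) != 1:
            break
        shared.append(level[0])
    if not shared:
        return UNASSIGNED
    return Lineage(tuple(shared))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _as_handle(stream):
    if isinstance(stream, str) and "\n" in stream:
        return io.StringIO(stream)
    if hasattr(stream, "read"):
        return stream
    return open(stream)


def parse_protein_fasta(stream) -> dict:
    """Read a protein FASTA into ``{gene_id: sequence}``.

    The header token up to the first whitespace is the gene id.  Sequences
    are uppercased and a terminal stop ``*`` is stripped.  Duplicate ids and
    empty sequences are hard errors.
    """
    proteome: dict = {}
    handle = _as_handle(stream)
    for record in SeqIO.parse(handle, "fasta"):
        gene_id = record.id
        if gene_id in proteome:
            raise ValueError(f"duplicate gene_id in FASTA: {gene_id}")
        seq = str(record.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise ValueError(f"empty sequence for gene {gene_id}")
        bad = set(seq) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"gene {gene_id}: illegal residues {sorted(bad)}")
        proteome[gene_id] = seq
    return proteome


def write_protein_fasta(proteome: Mapping[str, str], path_or_handle) -> None:
    records = [SeqRecord(Seq(seq), id=gene_id, description="")
               for gene_id, seq in proteome.items()]
    if hasattr(path_or_handle, "write"):
        SeqIO.write(records, path_or_handle, "fasta")
    else:
        with open(path_or_handle, "w") as fh:
            SeqIO.write(records, fh, "fasta")


def parse_profile_hits(stream,
                       cutoffs: Optional[Mapping[str, float]] = None,
                       default_cutoff: Optional[float] = None) -> list:
    """Read an hmmsearch ``--domtblout``-dialect table into ``ProfileHit``s.

    Columns used: target name (gene), query name (profile), full-sequence
    E-value and bit score.  Hits scoring below their profile's cutoff are
    dropped.  When per-profile ``cutoffs`` are given, hits for profiles not
    listed are kept with a warning; when only ``default_cutoff`` is given it
    applies to every profile.
    """
    hits: list = []
    unknown_warned: set = set()
    handle = _as_handle(stream)
    for lineno, line in enumerate(handle, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 8:
            raise ValueError(f"unparseable hit-table row at line {lineno}")
        gene_id, profile = parts[0], parts[3]
        try:
            e_value = float(parts[6])
            bit_score = float(parts[7])
        except ValueError as exc:
            raise ValueError(
                f"unparseable score fields at line {lineno}") from exc
        if cutoffs is not None:
            if profile in cutoffs:
                if bit_score < cutoffs[profile]:
                    continue
            else:
                if profile not in unknown_warned:
                    logger.warning("no cutoff for profile %r; keeping hits",
                                   profile)
                    unknown_warned.add(profile)
        elif default_cutoff is not None and bit_score < default_cutoff:
            continue
        hits.append(ProfileHit(gene_id, profile, bit_score, e_value))
    return hits


def write_profile_hits(hits: Iterable[ProfileHit], path_or_handle) -> None:
    """Write hits back out in the domain-table dialect ``parse_profile_hits`` reads."""
    fh = path_or_handle if hasattr(path_or_handle, "write") else open(
        path_or_handle, "w")
    try:
        fh.write("# target_name accession tlen query_name accession qlen "
                 "evalue score bias\n")
        for h in hits:
            fh.write(f"{h.gene_id} - 0 {h.profile} - 0 "
                     f"{h.e_value:g} {h.bit_score:g} 0.0\n")
    finally:
        if fh is not path_or_handle:
            fh.close()


def parse_coverage_table(stream) -> pd.DataFrame:
    """Read a scaffold x sample mean-depth TSV.

    Returns a DataFrame indexed by scaffold id with one column per sample.
    Missing cells become 0 with a warning; negative depths and duplicated
    scaffold rows are hard errors.
    """
    df = pd.read_csv(_as_handle(stream), sep="\t", index_col=0,
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated scaffold rows in coverage table: {dupes}")
    if df.isna().any().any():
        logger.warning("coverage table has %d missing cells; treated as 0",
                       int(df.isna().sum().sum()))
        df = df.fillna(0.0)
    df = df.astype(float)
    if (df.values < 0).any():
        raise ValueError("negative depth in coverage table")
    return df


def write_coverage_table(depths: pd.DataFrame, path_or_handle) -> None:
    depths.to_csv(path_or_handle, sep="\t", index_label="scaffold_id")


def parse_bin_membership(stream) -> dict:
    """Read a two-column (bin_id, scaffold_id) TSV into ``{bin_id: set}``.

    A scaffold assigned to two bins is a hard error.
    """
    df = pd.read_csv(_as_handle(stream), sep="\t", dtype=str)
    if list(df.columns[:2]) != ["bin_id", "scaffold_id"]:
        raise ValueError("bin membership table must have columns "
                         "bin_id, scaffold_id")
    seen: dict = {}
    bins: dict = {}
    for bin_id, scaffold_id in zip(df["bin_id"], df["scaffold_id"]):
        if scaffold_id in seen and seen[scaffold_id] != bin_id:
            raise ValueError(
                f"scaffold {scaffold_id} assigned to bins "
                f"{seen[scaffold_id]} and {bin_id}")
        seen[scaffold_id] = bin_id
        bins.setdefault(bin_id, set()).add(scaffold_id)
    return bins


def write_bin_membership(bins: Mapping[str, Iterable[str]], path_or_handle
                         ) -> None:
    rows = [(b, s) for b in sorted(bins) for s in sorted(bins[b])]
    pd.DataFrame(rows, columns=["bin_id", "scaffold_id"]).to_csv(
        path_or_handle, sep="\t", index=False)


def parse_gene_calls(stream) -> list:
    """Read CDS features from GFF3 into ordered ``GeneCall`` records.

    The ``ID`` attribute is the gene id.  Ordinals are assigned per scaffold
    by ascending start coordinate, irrespective of strand.
    """
    if hasattr(stream, "read"):
        text = stream.read()
    elif isinstance(stream, str) and "\n" in stream:
        text = stream
    else:
        with open(stream) as fh:
            text = fh.read()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        db = gffutils.create_db(text, dbfn=":memory:", from_string=True,
                                merge_strategy="error", keep_order=True)
    calls = []
    for feat in db.features_of_type("CDS"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        calls.append(GeneCall(gene_id=gene_id, scaffold_id=feat.seqid,
                              start=feat.start, end=feat.end,
                              strand=feat.strand))
    assign_ordinals(calls)
    return calls


def assign_ordinals(calls: Sequence[GeneCall]) -> None:
    """Assign per-scaffold ordinals in place, by ascending start coordinate."""
    by_scaffold: dict = {}
    for call in calls:
        by_scaffold.setdefault(call.scaffold_id, []).append(call)
    for group in by_scaffold.values():
        group.sort(key=lambda c: (c.start, c.end, c.gene_id))
        for i, call in enumerate(group):
            call.ordinal = i


def write_gene_calls(calls: Iterable[GeneCall], path_or_handle) -> None:
    fh = path_or_handle if hasattr(path_or_handle, "write") else open(
        path_or_handle, "w")
    try:
        fh.write("##gff-version 3\n")
        for c in calls:
            fh.write(f"{c.scaffold_id}\tgenopotential\tCDS\t{c.start}\t"
                     f"{c.end}\t.\t{c.strand}\t0\tID={c.gene_id}\n")
    finally:
        if fh is not path_or_handle:
            fh.close()


def parse_nucleotide_fasta(stream) -> dict:
    """Read scaffold nucleotide sequences into ``{scaffold_id: sequence}``."""
    seqs: dict = {}
    for record in SeqIO.parse(_as_handle(stream), "fasta"):
        if record.id in seqs:
            raise ValueError(f"duplicate scaffold id in FASTA: {record.id}")
        seqs[record.id] = str(record.seq).upper()
    return seqs


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def map_genes_to_bins(calls: Iterable[GeneCall],
                      bins: Mapping[str, set]) -> dict:
    """Map gene_id -> bin_id via scaffold membership (unbinned genes absent)."""
    scaffold_to_bin: dict = {}
    for bin_id, scaffolds in bins.items():
        for s in scaffolds:
            if s in scaffold_to_bin and scaffold_to_bin[s] != bin_id:
                raise ValueError(f"scaffold {s} in two bins")
            scaffold_to_bin[s] = bin_id
    return {c.gene_id: scaffold_to_bin[c.scaffold_id]
            for c in calls if c.scaffold_id in scaffold_to_bin}
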