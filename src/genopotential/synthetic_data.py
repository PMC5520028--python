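"""Seeded synthetic-community generator with planted ground truth.

Every generator here is a pure function of its arguments including the
seed, and every emitted entity carries a truth record, so each downstream
stage can be tested against exact planted answers.

Motif planting uses a guarded residue alphabet: background residues are
drawn from the 18 standard amino acids excluding cysteine and histidine,
and motif middles likewise, so a protein contains exactly the CXXCH windows
planted in it — a window needs C at its first and fourth and H at its fifth
position, and those letters occur only inside planted payloads.  A
"realistic" full-alphabet mode exists for oracle-versus-implementation
testing; there the truth count is an independent brute-force scan.

Nucleotide replicates are made by point substitution at a stated per-base
rate, so the expected pairwise identity of a replicate and its source is
exactly one minus the rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core_model import (GeneCall, ProfileHit, Thresholds, assign_ordinals,
                         write_gene_calls, write_profile_hits)
from .community import MarkerSet
from .pathway_profile import PathwayRule, load_rulebook

FULL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: background alphabet for guarded motif planting (no C, no H)
GUARD_AA = "ADEFGIKLMNPQRSTVWY"
DNA = "ACGT"

#: 51 conserved single-copy marker gene labels (rpS3 deliberately excluded —
#: it is the community-accounting marker, not a QC marker here)
DEFAULT_MARKERS = tuple(
    [f"rpL{i}" for i in (1, 2, 3, 4, 5, 6, 9, 10, 11, 12, 13, 14, 15, 16, 17,
                         18, 19, 20, 21, 22, 23, 24, 25, 27, 28, 29, 30, 32,
                         33, 34, 35, 36)]
    + [f"rpS{i}" for i in (2, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 15, 16, 17,
                           18, 19, 20)]
    + ["infC", "pheS"])

DEFAULT_MARKER_SET = MarkerSet(domain="bacteria", markers=DEFAULT_MARKERS)


@dataclass
class SyntheticTruth:
    """Planted ground truth serialized alongside every fixture bundle."""

    planted_motifs: dict = field(default_factory=dict)       # bin -> {gene: n}
    hydrogenase_labels: dict = field(default_factory=dict)   # bin -> {gene: label}
    marker_complement: dict = field(default_factory=dict)    # bin -> {present,duplicated,absent}
    pathway_status: dict = field(default_factory=dict)       # bin -> {pathway: status}
    pathway_gene_counts: dict = field(default_factory=dict)  # bin -> {pathway: n}
    abundance: dict = field(default_factory=dict)            # sample -> {organism: frac}
    replicate_map: dict = field(default_factory=dict)        # rep bin -> {source, rate, ...}
    rps3_genes: dict = field(default_factory=dict)           # organism -> {gene, scaffold}
    rps3_clusters: list = field(default_factory=list)        # [{representative, members, binned}]
    derep_clusters: list = field(default_factory=list)       # [sorted member lists]
    rnf_bins: list = field(default_factory=list)
    unbinned_organisms: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _random_string(rng: np.random.Generator, alphabet: str, n: int) -> str:
    letters = np.frombuffer(alphabet.encode(), dtype=np.uint8)
    return rng.choice(letters, size=n).tobytes().decode()


def _brute_count_cxxch(protein: str) -> int:
    """Independent position-by-position CXXCH scan (the test oracle)."""
    n = 0
    for i in range(len(protein) - 4):
        if (protein[i] == "C" and protein[i + 3] == "C"
                and protein[i + 4] == "H"
                and protein[i + 1] not in "X*" and protein[i + 2] not in "X*"):
            n += 1
    return n


def _mutate_string(rng: np.random.Generator, seq: str, rate: float,
                   alphabet: str) -> Tuple[str, int]:
    """Point-substitute each position with probability ``rate``.

    Substitutions always change the letter (drawn uniformly from the other
    alphabet letters), so the returned substitution count is exact.
    """
    if rate == 0.0:
        return seq, 0
    letters = np.frombuffer(alphabet.encode(), dtype=np.uint8)
    lookup = np.full(256, -1, dtype=np.int64)
    lookup[letters] = np.arange(len(letters))
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    idx = np.nonzero(hit)[0]
    if idx.size:
        cur = lookup[arr[idx]]
        shift = rng.integers(1, len(letters), size=idx.size)
        arr[idx] = letters[(cur + shift) % len(letters)]
    return arr.tobytes().decode(), int(idx.size)


# ---------------------------------------------------------------------------
# proteomes with planted motifs
# ---------------------------------------------------------------------------

def generate_proteome(n_proteins: int,
                      length_range: Tuple[int, int] = (80, 300),
                      motif_counts=0,
                      seed: int = 0,
                      realistic: bool = False,
                      id_prefix: str = "prot"
                      ) -> Tuple[str, SyntheticTruth]:
    """Emit a FASTA of proteins each carrying a known number of CXXCH motifs.

    ``motif_counts`` may be a single int, a per-protein sequence of ints, or
    a ``{count: probability}`` distribution.  In the default guarded mode
    the planted count is exact; in ``realistic`` mode background residues
    come from the full alphabet and the truth count is a brute-force scan.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(motif_counts, Mapping):
        ks = sorted(motif_counts)
        probs = np.array([motif_counts[k] for k in ks], dtype=float)
        probs = probs / probs.sum()
        counts = [int(rng.choice(ks, p=probs)) for _ in range(n_proteins)]
    elif isinstance(motif_counts, int):
        counts = [motif_counts] * n_proteins
    else:
        counts = [int(c) for c in motif_counts]
        if len(counts) != n_proteins:
            raise ValueError("motif_counts sequence length != n_proteins")

    background = FULL_AA if realistic else GUARD_AA
    lines = []
    truth = SyntheticTruth()
    truth.planted_motifs["proteome"] = {}
    lo, hi = length_range
    for i in range(n_proteins):
        k = counts[i]
        length = int(rng.integers(lo, hi + 1))
        if 5 * k > length:
            raise ValueError(
                f"protein {i}: {k} motifs (payload {5 * k}) exceed "
                f"length {length}")
        seq = list(_random_string(rng, background, length))
        # non-overlapping starts via the gap construction
        slack = length - 5 * k
        offsets = np.sort(rng.integers(0, slack + 1, size=k)) if k else []
        for j in range(k):
            start = int(offsets[j]) + 5 * j
            seq[start:start + 5] = ["C", *_random_string(rng, GUARD_AA, 2),
                                    "C", "H"]
        protein = "".join(seq)
        gene_id = f"{id_prefix}_{i:05d}"
        lines.append(f">{gene_id}\n{protein}")
        truth.planted_motifs["proteome"][gene_id] = (
            _brute_count_cxxch(protein) if realistic else k)
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# hydrogenase operon layouts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OperonLayout:
    """One planted scaffold layout around a catalytic hydrogenase gene.

    ``neighbors`` lists (role, co_oriented) pairs in the catalytic gene's
    reading direction; role is ``hydB``, ``hydC`` or ``x`` (a hit-free
    gene).  ``truncated`` puts the scaffold end right after the listed
    neighbors; otherwise the window is padded with hit-free genes.
    """

    name: str
    catalytic: str = "FeFe_GA"
    strand: str = "+"
    neighbors: tuple = ()
    truncated: bool = False
    n_upstream: int = 1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")
        for role, _ in self.neighbors:
            if role not in ("hydB", "hydC", "x"):
                raise ValueError(f"unknown layout token {role!r}")


_NON_A_LABELS = {"FeFe_GB": "B", "FeFe_GC": "C", "Fe_hmd": "Fe",
                 "NiFe_G1": "NiFe_1", "NiFe_G2": "NiFe_2",
                 "NiFe_G3": "NiFe_3", "NiFe_G4": "NiFe_4"}


def layout_truth_label(layout: OperonLayout, window: int = 3) -> str:
    """Planted subgroup label for a layout (independent of the classifier)."""
    if layout.catalytic != "FeFe_GA":
        try:
            return _NON_A_LABELS[layout.catalytic]
        except KeyError:
            raise ValueError(f"unknown catalytic token {layout.catalytic!r}")
    roles = {role for role, co in layout.neighbors[:window]
             if co and role in ("hydB", "hydC")}
    if {"hydB", "hydC"} <= roles:
        return "A3"
    if layout.truncated and len(layout.neighbors) < window:
        return "A_unresolved"
    return "A1"


def generate_operon_fixture(layouts: Sequence[OperonLayout],
                            seed: int = 0,
                            window: int = 3
                            ) -> Tuple[str, str, SyntheticTruth]:
    """Emit one scaffold per layout as (GFF3 text, hit-table text, truth).

    The truth maps each catalytic gene to its planted label in
    {A1, A3, A_unresolved, B, C, NiFe_x, Fe}.
    """
    rng = np.random.default_rng(seed)
    calls: list = []
    hits: list = []
    truth = SyntheticTruth()
    names = [l.name for l in layouts]
    if len(set(names)) != len(names):
        raise ValueError("layout names must be unique")
    for layout in layouts:
        scaffold = layout.name
        flip = {"+": "-", "-": "+"}
        # reading-direction list of (profile_or_None, strand)
        reading = [(None, layout.strand)] * layout.n_upstream
        reading.append((layout.catalytic, layout.strand))
        cat_reading_idx = len(reading) - 1
        for role, co in layout.neighbors:
            strand = layout.strand if co else flip[layout.strand]
            reading.append((role if role != "x" else None, strand))
        if not layout.truncated:
            pad = max(0, window - len(layout.neighbors))
            reading.extend([(None, layout.strand)] * pad)
        physical = reading if layout.strand == "+" else reading[::-1]
        for j, (profile, strand) in enumerate(physical):
            start = 1 + j * 350
            gene_id = f"{scaffold}_g{j}"
            calls.append(GeneCall(gene_id=gene_id, scaffold_id=scaffold,
                                  start=start, end=start + 299,
                                  strand=strand))
            if profile is not None:
                hits.append(ProfileHit(gene_id, profile,
                                       bit_score=float(rng.integers(150, 300)),
                                       e_value=1e-50))
            if layout.strand == "+" and j == cat_reading_idx:
                cat_gene = gene_id
            if layout.strand == "-" and j == len(physical) - 1 - cat_reading_idx:
                cat_gene = gene_id
        truth.hydrogenase_labels.setdefault(scaffold, {})[cat_gene] = \
            layout_truth_label(layout, window)
    assign_ordinals(calls)
    import io as _io
    gff = _io.StringIO()
    write_gene_calls(calls, gff)
    tbl = _io.StringIO()
    write_profile_hits(hits, tbl)
    return gff.getvalue(), tbl.getvalue(), truth


def exhaustive_layout_grid(window: int = 3) -> list:
    """Every (strand x truncation x neighbor-role) layout up to the window.

    Neighbor roles range over hit-free, co-oriented hydB/hydC and
    counter-oriented hydB/hydC, for 0..window downstream genes, on both
    strands, with and without scaffold-end truncation — the full decision
    surface of the Group A rule (hundreds of layouts).
    """
    roles = [("x", True), ("hydB", True), ("hydC", True),
             ("hydB", False), ("hydC", False)]
    layouts = []
    i = 0
    for strand in "+-":
        for truncated in (False, True):
            for n in range(window + 1):
                combos = [()] if n == 0 else None
                if combos is None:
                    combos = [()]
                    for _ in range(n):
                        combos = [c + (r,) for c in combos for r in roles]
                for combo in combos:
                    layouts.append(OperonLayout(
                        name=f"grid_{i:04d}", catalytic="FeFe_GA",
                        strand=strand, neighbors=combo, truncated=truncated))
                    i += 1
    return layouts


# ---------------------------------------------------------------------------
# whole-community bundles
# ---------------------------------------------------------------------------

_STATUS_COMPLETE, _STATUS_PARTIAL, _STATUS_ABSENT = \
    "complete", "partial", "absent"


def _truth_eval_rule(genes: set, rule: PathwayRule) -> str:
    """Independent (generator-side) clause evaluation for truth records."""
    sat = []
    for clause in rule.clauses:
        present = bool(clause.alternatives & genes)
        sat.append((not present) if clause.negated else present)
    pos_sat = [s for s, c in zip(sat, rule.clauses) if not c.negated and s]
    if all(sat) and pos_sat:
        return _STATUS_COMPLETE
    if not pos_sat:
        return _STATUS_ABSENT
    return _STATUS_PARTIAL


@dataclass
class _GeneSpec:
    profiles: tuple      # profile hits to emit for this gene
    protein: str
    planted_motifs: int = 0


@dataclass
class CommunityBundle:
    """In-memory synthetic community: every file the pipeline reads + truth."""

    seed: int
    proteins: dict                 # gene -> aa sequence
    gene_calls: list
    hits: list
    scaffold_seqs: dict            # scaffold -> nucleotide sequence
    coverage: pd.DataFrame
    bin_membership: dict           # bin -> set of scaffolds
    marker_set: MarkerSet
    truth: SyntheticTruth

    def write(self, outdir) -> dict:
        """Serialize the bundle; returns the path map a RunConfig needs."""
        import os
        from .core_model import (write_bin_membership, write_coverage_table,
                                 write_protein_fasta)
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "proteins": os.path.join(outdir, "proteins.faa"),
            "scaffolds": os.path.join(outdir, "scaffolds.fna"),
            "genes": os.path.join(outdir, "genes.gff"),
            "hits": os.path.join(outdir, "hits.domtbl"),
            "coverage": os.path.join(outdir, "coverage.tsv"),
            "bins": os.path.join(outdir, "bins.tsv"),
            "markers": os.path.join(outdir, "markers.tsv"),
            "truth": os.path.join(outdir, "truth.json"),
        }
        write_protein_fasta(self.proteins, paths["proteins"])
        write_protein_fasta(self.scaffold_seqs, paths["scaffolds"])
        write_gene_calls(self.gene_calls, paths["genes"])
        write_profile_hits(self.hits, paths["hits"])
        write_coverage_table(self.coverage, paths["coverage"])
        write_bin_membership(self.bin_membership, paths["bins"])
        with open(paths["markers"], "w") as fh:
            fh.write("marker\n")
            for m in self.marker_set.markers:
                fh.write(m + "\n")
        self.truth.to_json(paths["truth"])
        return paths


def _greedy_hamming_clusters(seqs: Mapping[str, str],
                             identity_threshold: float) -> list:
    """Greedy centroid clustering by Hamming identity (equal-length seqs).

    Mirrors the ordering contract of the rpS3 clusterer so planted truth is
    exact, while measuring identity by direct position comparison.
    """
    order = sorted(seqs, key=lambda k: (-len(seqs[k]), k))
    clusters: list = []
    for sid in order:
        seq = seqs[sid]
        placed = False
        for centroid, members in clusters:
            other = seqs[centroid]
            if len(other) != len(seq):
                continue
            matches = sum(a == b for a, b in zip(seq, other))
            if matches / len(seq) >= identity_threshold:
                members.append(sid)
                placed = True
                break
        if not placed:
            clusters.append((sid, [sid]))
    return clusters


def generate_community(n_bins: int = 12,
                       marker_set: Optional[MarkerSet] = None,
                       pathway_rules: Optional[Sequence[PathwayRule]] = None,
                       n_samples: int = 4,
                       abundance_sigma: float = 1.0,
                       replicate_spec: Sequence[Tuple[int, float]] = (),
                       seed: int = 0,
                       n_unbinned_rare: int = 3,
                       unbinned_abundance: float = 4e-4,
                       depth_const: float = 1000.0,
                       scaffolds_per_bin: int = 3,
                       scaffold_len: int = 12000,
                       thresholds: Optional[Thresholds] = None
                       ) -> CommunityBundle:
    """Build a toy community with planted truth for every pipeline stage.

    Each source bin gets a known single-copy-marker complement (hence known
    completeness/contamination), a drawn pathway-gene complement, planted
    multiheme cytochromes, optional hydrogenase operons (co-occurrence is
    planted so that A1 and Group B occur only alongside A3), and exactly one
    rpS3 gene.  ``replicate_spec`` lists ``(source_index, per_base_rate)``
    pairs producing point-mutated copies of source bins.  Scaffold depth is
    organism abundance times ``depth_const``, identical for all scaffolds of
    a bin, with per-sample abundances drawn log-normally; ``n_unbinned_rare``
    extra rpS3-bearing scaffolds are left out of every bin at a fixed rare
    abundance.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    for src, rate in replicate_spec:
        if not 0.0 <= rate <= 0.3:
            raise ValueError(f"mutation rate {rate} outside [0, 0.3]")
        if not 0 <= src < n_bins:
            raise ValueError(f"replicate source index {src} out of range")
    marker_set = marker_set or DEFAULT_MARKER_SET
    thr = thresholds or Thresholds()
    rules = list(pathway_rules) if pathway_rules is not None else load_rulebook()
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()

    proteins: dict = {}
    gene_calls: list = []
    hits: list = []
    scaffold_seqs: dict = {}
    bin_membership: dict = {}
    source_specs: dict = {}   # bin -> list of block (list of _GeneSpec)

    def marker_protein():
        return _random_string(rng, GUARD_AA, 100)

    def mhc_protein(k: int) -> str:
        length = 5 * k + 120
        seq = list(_random_string(rng, GUARD_AA, length))
        slack = length - 5 * k
        offsets = np.sort(rng.integers(0, slack + 1, size=k)) if k else []
        for j in range(k):
            start = int(offsets[j]) + 5 * j
            seq[start:start + 5] = ["C", *_random_string(rng, GUARD_AA, 2),
                                    "C", "H"]
        return "".join(seq)

    source_ids = [f"bin_{i:02d}" for i in range(n_bins)]
    for bin_id in source_ids:
        blocks: list = []
        labels: dict = {}

        # hydrogenase plan — A1/B planted only alongside A3 so the expected
        # co-occurrence structure holds by construction
        has_a3 = rng.random() < 0.5
        plan = []
        if has_a3:
            plan.append(("A3", ["FeFe_GA", "hydB", "hydC"]))
            if rng.random() < 0.4:
                plan.append(("A1", ["FeFe_GA"]))
            if rng.random() < 0.35:
                plan.append(("B", ["FeFe_GB"]))
            if rng.random() < 0.3:
                plan.append(("C", ["FeFe_GC"]))
            has_rnf = rng.random() < 0.75
        else:
            if rng.random() < 0.4:
                plan.append(("NiFe_1", ["NiFe_G1"]))
            has_rnf = rng.random() < 0.15
        for label, profiles in plan:
            block = [_GeneSpec((p,), marker_protein()) for p in profiles]
            # trailing hit-free genes keep the downstream window inert
            block += [_GeneSpec((), marker_protein())
                      for _ in range(thr.operon_window)]
            blocks.append((block, label))
        if has_rnf:
            blocks.append(([_GeneSpec(("rnfC",), marker_protein())], None))

        # marker complement
        n_present = int(round(rng.uniform(0.55, 1.0) * len(marker_set.markers)))
        present = sorted(rng.choice(marker_set.markers, size=n_present,
                                    replace=False).tolist())
        dup_rate = rng.uniform(0.0, 0.15)
        duplicated = sorted(m for m in present if rng.random() < dup_rate)
        truth.marker_complement[bin_id] = {
            "present": present,
            "duplicated": duplicated,
            "absent": sorted(set(marker_set.markers) - set(present)),
        }
        for m in present:
            blocks.append(([_GeneSpec((m,), marker_protein())], None))
        for m in duplicated:
            blocks.append(([_GeneSpec((m,), marker_protein())], None))

        # pathway complement
        for rule in rules:
            if rule.mode == "count":
                n = int(rng.integers(0, len(rule.count_genes) + 1))
                for g in sorted(rng.choice(sorted(rule.count_genes), size=n,
                                           replace=False).tolist()):
                    blocks.append(([_GeneSpec((g,), marker_protein())], None))
                continue
            positive = [c for c in rule.clauses if not c.negated]
            negated = [c for c in rule.clauses if c.negated]
            draw = rng.random()
            chosen: list = []
            if draw < 0.3:  # aim complete
                chosen = [sorted(c.alternatives)[
                    int(rng.integers(0, len(c.alternatives)))]
                    for c in positive]
            elif draw < 0.55 and len(positive) >= 2:  # aim partial
                k = int(rng.integers(1, len(positive)))
                picked = rng.choice(len(positive), size=k, replace=False)
                chosen = [sorted(positive[i].alternatives)[0] for i in picked]
            if negated and rng.random() < 0.15:
                chosen.extend(sorted(negated[0].alternatives)[:1])
            for g in chosen:
                blocks.append(([_GeneSpec((g,), marker_protein())], None))

        # multiheme cytochromes (guarded: counts are exact)
        motif_plan = ([int(rng.integers(10, 25))
                       for _ in range(int(rng.integers(0, 6)))]
                      + [int(rng.integers(0, 10))
                         for _ in range(int(rng.integers(2, 5)))])
        for k in motif_plan:
            blocks.append(([_GeneSpec((), mhc_protein(k), planted_motifs=k)],
                           None))

        # exactly one rpS3
        blocks.append(([_GeneSpec(("rpS3",), _random_string(rng, GUARD_AA,
                                                            200))], None))
        source_specs[bin_id] = (blocks, labels)

    # replicate bins: mutated copies of their source's layout
    replicate_ids = []
    for ri, (src_idx, rate) in enumerate(replicate_spec):
        source = source_ids[src_idx]
        rep_id = f"{source}_rep{ri}"
        replicate_ids.append(rep_id)
        truth.replicate_map[rep_id] = {"source": source, "rate": float(rate)}

    # --- lay out genes on scaffolds, bin by bin -----------------------------
    def place_bin(bin_id: str, blocks: list) -> None:
        scaffolds = [f"{bin_id}_s{j}" for j in range(scaffolds_per_bin)]
        bin_membership[bin_id] = set(scaffolds)
        truth.planted_motifs[bin_id] = {}
        truth.hydrogenase_labels[bin_id] = {}
        s_idx, pos, g_idx = 0, 1, 0
        for block, label in blocks:
            span = sum(3 * len(spec.protein) + 20 for spec in block)
            if pos + span > scaffold_len:
                s_idx += 1
                pos = 1
                if s_idx >= scaffolds_per_bin:
                    raise ValueError(
                        f"bin {bin_id}: genes exceed scaffold capacity")
            first = True
            for spec in block:
                gene_id = f"{bin_id}_g{g_idx:04d}"
                g_idx += 1
                end = pos + 3 * len(spec.protein) - 1
                gene_calls.append(GeneCall(gene_id=gene_id,
                                           scaffold_id=scaffolds[s_idx],
                                           start=pos, end=end, strand="+"))
                pos = end + 21
                proteins[gene_id] = spec.protein
                for profile in spec.profiles:
                    hits.append(ProfileHit(gene_id, profile,
                                           bit_score=200.0, e_value=1e-60))
                    if profile == "rpS3":
                        truth.rps3_genes[bin_id] = {
                            "gene": gene_id, "scaffold": scaffolds[s_idx]}
                if spec.planted_motifs or not spec.profiles:
                    truth.planted_motifs[bin_id][gene_id] = \
                        spec.planted_motifs
                if label is not None and first and spec.profiles:
                    truth.hydrogenase_labels[bin_id][gene_id] = label
                first = False

    for bin_id in source_ids:
        blocks, _ = source_specs[bin_id]
        place_bin(bin_id, blocks)
        for j in range(scaffolds_per_bin):
            scaffold_seqs[f"{bin_id}_s{j}"] = _random_string(
                rng, DNA, scaffold_len)

    # replicates copy the source's gene layout; scaffolds and the rpS3
    # protein are point-mutated at the stated rate
    for rep_id in replicate_ids:
        source = truth.replicate_map[rep_id]["source"]
        rate = truth.replicate_map[rep_id]["rate"]
        scaffolds = [f"{rep_id}_s{j}" for j in range(scaffolds_per_bin)]
        bin_membership[rep_id] = set(scaffolds)
        truth.planted_motifs[rep_id] = {}
        truth.hydrogenase_labels[rep_id] = {}
        total_subs = 0
        for j in range(scaffolds_per_bin):
            mutated, subs = _mutate_string(
                rng, scaffold_seqs[f"{source}_s{j}"], rate, DNA)
            scaffold_seqs[scaffolds[j]] = mutated
            total_subs += subs
        truth.replicate_map[rep_id]["scaffold_substitutions"] = total_subs
        truth.replicate_map[rep_id]["scaffold_bases"] = (
            scaffolds_per_bin * scaffold_len)
        rename = {}
        for call in [c for c in gene_calls
                     if c.scaffold_id.rsplit("_s", 1)[0] == source]:
            new_id = f"{rep_id}_g{call.gene_id.split('_g')[-1]}"
            rename[call.gene_id] = new_id
            suffix = call.scaffold_id.rsplit("_s", 1)[1]
            gene_calls.append(GeneCall(
                gene_id=new_id, scaffold_id=f"{rep_id}_s{suffix}",
                start=call.start, end=call.end, strand=call.strand))
        for old_id, new_id in rename.items():
            protein = proteins[old_id]
            is_rps3 = truth.rps3_genes[source]["gene"] == old_id
            if is_rps3:
                protein, rps3_subs = _mutate_string(rng, protein, rate,
                                                    GUARD_AA)
                truth.replicate_map[rep_id]["rps3_substitutions"] = rps3_subs
                truth.rps3_genes[rep_id] = {
                    "gene": new_id,
                    "scaffold": f"{rep_id}_s" + next(
                        c.scaffold_id.rsplit("_s", 1)[1]
                        for c in gene_calls if c.gene_id == new_id)}
            proteins[new_id] = protein
            if old_id in truth.planted_motifs[source]:
                truth.planted_motifs[rep_id][new_id] = \
                    truth.planted_motifs[source][old_id]
            if old_id in truth.hydrogenase_labels[source]:
                truth.hydrogenase_labels[rep_id][new_id] = \
                    truth.hydrogenase_labels[source][old_id]
        for h in [h for h in hits if h.gene_id in rename]:
            hits.append(ProfileHit(rename[h.gene_id], h.profile,
                                   h.bit_score, h.e_value))
        truth.marker_complement[rep_id] = truth.marker_complement[source]

    # unbinned rare organisms: one rpS3-bearing scaffold each
    unbinned_ids = [f"unbinned_{i}" for i in range(n_unbinned_rare)]
    for uid in unbinned_ids:
        scaffold = f"{uid}_s0"
        scaffold_seqs[scaffold] = _random_string(rng, DNA, 2000)
        gene_id = f"{uid}_rps3"
        gene_calls.append(GeneCall(gene_id=gene_id, scaffold_id=scaffold,
                                   start=1, end=600, strand="+"))
        proteins[gene_id] = _random_string(rng, GUARD_AA, 200)
        hits.append(ProfileHit(gene_id, "rpS3", 200.0, 1e-60))
        truth.rps3_genes[uid] = {"gene": gene_id, "scaffold": scaffold}
        truth.unbinned_organisms.append(uid)

    assign_ordinals(gene_calls)

    # --- abundances and depth ----------------------------------------------
    organisms = source_ids + replicate_ids
    samples = [f"sample_{s}" for s in range(n_samples)]
    rare_total = n_unbinned_rare * unbinned_abundance
    if rare_total >= 1.0:
        raise ValueError("unbinned abundance mass must stay below 1")
    depth_rows: dict = {}
    for sample in samples:
        weights = rng.lognormal(mean=0.0, sigma=abundance_sigma,
                                size=len(organisms))
        rel = weights / weights.sum() * (1.0 - rare_total)
        truth.abundance[sample] = {}
        for org, r in zip(organisms, rel):
            truth.abundance[sample][org] = float(r)
        for uid in unbinned_ids:
            truth.abundance[sample][uid] = float(unbinned_abundance)
    for scaffold in scaffold_seqs:
        org = (scaffold.rsplit("_s", 1)[0])
        depth_rows[scaffold] = {
            sample: truth.abundance[sample][org] * depth_const
            for sample in samples}
    coverage = pd.DataFrame.from_dict(depth_rows, orient="index")[samples]
    coverage.index.name = "scaffold_id"

    # --- truth-side derived answers ----------------------------------------
    # pathway status, from the final per-bin label sets
    gene_bin = {}
    scaffold_bin = {s: b for b, ss in bin_membership.items() for s in ss}
    for call in gene_calls:
        if call.scaffold_id in scaffold_bin:
            gene_bin[call.gene_id] = scaffold_bin[call.scaffold_id]
    labels_by_bin: dict = {b: set() for b in bin_membership}
    for h in hits:
        if h.gene_id in gene_bin:
            labels_by_bin[gene_bin[h.gene_id]].add(h.profile)
    # Rnf presence from the final hit set: the pathway draw can add rnfC
    # genes beyond the hydrogenase plan's, and both count
    rnf_labels = {"rnfA", "rnfB", "rnfC", "rnfD", "rnfE", "rnfG"}
    truth.rnf_bins = sorted(b for b, labels in labels_by_bin.items()
                            if labels & rnf_labels)
    for bin_id in sorted(bin_membership):
        truth.pathway_status[bin_id] = {}
        truth.pathway_gene_counts[bin_id] = {}
        for rule in rules:
            if rule.mode == "count":
                truth.pathway_gene_counts[bin_id][rule.pathway] = len(
                    rule.count_genes & labels_by_bin[bin_id])
            else:
                truth.pathway_status[bin_id][rule.pathway] = \
                    _truth_eval_rule(labels_by_bin[bin_id], rule)

    # dereplication clusters, from actual substitution counts
    parent = {b: b for b in bin_membership}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for rep_id, info in truth.replicate_map.items():
        identity = 1.0 - info["scaffold_substitutions"] / info["scaffold_bases"]
        if identity >= thr.derep_identity:
            parent[find(rep_id)] = find(info["source"])
    groups: dict = {}
    for b in bin_membership:
        groups.setdefault(find(b), []).append(b)
    truth.derep_clusters = sorted(sorted(g) for g in groups.values())

    # rpS3 clusters, by Hamming identity under the clusterer's ordering rule
    rps3_seqs = {truth.rps3_genes[org]["gene"]: proteins[
        truth.rps3_genes[org]["gene"]] for org in truth.rps3_genes}
    gene_to_org = {v["gene"]: org for org, v in truth.rps3_genes.items()}
    for centroid, members in _greedy_hamming_clusters(
            rps3_seqs, thr.rps3_cluster_identity):
        scaffold = truth.rps3_genes[gene_to_org[centroid]]["scaffold"]
        truth.rps3_clusters.append({
            "representative": centroid,
            "members": sorted(members),
            "binned": scaffold in scaffold_bin,
        })

    return CommunityBundle(seed=seed, proteins=proteins,
                           gene_calls=gene_calls, hits=hits,
                           scaffold_seqs=scaffold_seqs, coverage=coverage,
                           bin_membership=bin_membership,
                           marker_set=marker_set, truth=truth)
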