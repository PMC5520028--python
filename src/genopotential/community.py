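"""Bin QC, dereplication, rpS3 community accounting and alignment prep.

Completeness and contamination are estimated against a set of conserved
single-copy marker genes: completeness is the fraction of markers detected
at least once, contamination the fraction detected in two or more copies.
Near-identical bins recovered from different samples are collapsed by
single-linkage clustering over pairwise nucleotide identity.  Community
structure is counted organism-by-organism by clustering the ribosomal
protein S3 (rpS3), a single-copy marker that assembles reliably from
metagenomes, and ranking the clusters by scaffold read depth.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Set, Tuple

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .core_model import GenomeBin, MarkerSetError, ProfileHit, Thresholds

logger = logging.getLogger("genopotential")

GAP_CHARS = frozenset("-.")

#: k-mer size for the shared-seed prescreen in pairwise identity
_PRESCREEN_K = 21


@dataclass(frozen=True)
class MarkerSet:
    """A set of conserved single-copy marker gene labels for one domain."""

    domain: str
    markers: tuple

    def __post_init__(self) -> None:
        if not self.markers:
            raise MarkerSetError("empty marker set")
        if len(set(self.markers)) != len(self.markers):
            raise MarkerSetError("duplicate markers in marker set")


@dataclass
class DereplicationResult:
    clusters: list                 # list of frozenset of bin ids
    representative: dict           # frozenset -> bin_id

    def representative_of(self, bin_id: str) -> str:
        for cluster in self.clusters:
            if bin_id in cluster:
                return self.representative[cluster]
        raise KeyError(bin_id)

    def as_mapping(self) -> dict:
        """bin_id -> representative bin_id, for every input bin."""
        return {b: self.representative[c]
                for c in self.clusters for b in c}


# ---------------------------------------------------------------------------
# bin quality
# ---------------------------------------------------------------------------

def bin_quality(bin_: GenomeBin, hits: Iterable[ProfileHit],
                marker_set: MarkerSet,
                thresholds: Optional[Thresholds] = None
                ) -> Tuple[float, float, bool]:
    """Completeness/contamination of a bin from its single-copy marker hits.

    ``hits`` must already be restricted to the bin's genes.  Completeness is
    100 x |markers hit by >=1 gene| / |marker set|; contamination is
    100 x |markers hit by >=2 distinct genes| / |marker set|.  High quality
    means strictly >hq_min_completeness complete and <hq_max_contamination
    contaminated.
    """
    thr = thresholds or Thresholds()
    marker_labels = set(marker_set.markers)
    genes_per_marker: dict = {}
    for h in hits:
        if h.profile in marker_labels:
            genes_per_marker.setdefault(h.profile, set()).add(h.gene_id)
    n = len(marker_set.markers)
    present = sum(1 for g in genes_per_marker.values() if len(g) >= 1)
    duplicated = sum(1 for g in genes_per_marker.values() if len(g) >= 2)
    completeness = 100.0 * present / n
    contamination = 100.0 * duplicated / n
    hq = (completeness > thr.hq_min_completeness
          and contamination < thr.hq_max_contamination)
    return completeness, contamination, hq


def qc_bins(bins: Sequence[GenomeBin], hits: Iterable[ProfileHit],
            gene_bins: Mapping[str, str], marker_set: MarkerSet,
            thresholds: Optional[Thresholds] = None) -> list:
    """Run ``bin_quality`` for every bin, updating the bins in place."""
    per_bin: dict = {b.bin_id: [] for b in bins}
    for h in hits:
        bin_id = gene_bins.get(h.gene_id)
        if bin_id in per_bin:
            per_bin[bin_id].append(h)
    for b in bins:
        b.completeness, b.contamination, b.is_high_quality = bin_quality(
            b, per_bin[b.bin_id], marker_set, thresholds)
    return bins


# ---------------------------------------------------------------------------
# pairwise identity and dereplication
# ---------------------------------------------------------------------------

def _kmers(seq: str, k: int = _PRESCREEN_K) -> set:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def global_identity(a: str, b: str) -> float:
    """Global (NW) sequence identity: 1 - edit distance / longer length."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def pairwise_identity(scaffolds_a: Mapping[str, str],
                      scaffolds_b: Mapping[str, str]
                      ) -> Tuple[float, float]:
    """Estimate (identity, aligned fraction) between two bins' scaffolds.

    Scaffolds are matched greedily by shared k-mer seeds and scored by
    global alignment; identity is the match-length-weighted mean over
    matched scaffold pairs and the aligned fraction is matched length over
    the shorter genome's total length.
    """
    if not scaffolds_a or not scaffolds_b:
        raise ValueError("both bins need nucleotide scaffolds")
    len_a = sum(len(s) for s in scaffolds_a.values())
    len_b = sum(len(s) for s in scaffolds_b.values())
    shorter_total = min(len_a, len_b)
    # iterate the shorter side for symmetry
    if (len_a, sorted(scaffolds_a)) > (len_b, sorted(scaffolds_b)):
        scaffolds_a, scaffolds_b = scaffolds_b, scaffolds_a
    kmer_index = {sid: _kmers(seq) for sid, seq in scaffolds_b.items()}
    matched_len = 0
    weighted_identity = 0.0
    for sid in sorted(scaffolds_a):
        seq = scaffolds_a[sid]
        seed = _kmers(seq)
        best = None
        for other_id in sorted(scaffolds_b):
            if not (seed & kmer_index[other_id]):
                continue
            other = scaffolds_b[other_id]
            max_len = max(len(seq), len(other))
            res = edlib.align(seq, other, mode="NW", task="distance",
                              k=int(0.3 * max_len))
            if res["editDistance"] < 0:
                continue
            ident = 1.0 - res["editDistance"] / max_len
            if best is None or ident > best[0]:
                best = (ident, other_id)
        if best is not None:
            span = min(len(seq), len(scaffolds_b[best[1]]))
            matched_len += span
            weighted_identity += best[0] * span
    if matched_len == 0:
        return 0.0, 0.0
    return weighted_identity / matched_len, matched_len / shorter_total


def dereplicate(bins: Sequence[GenomeBin],
                identities: Mapping[frozenset, Tuple[float, float]],
                thresholds: Optional[Thresholds] = None
                ) -> DereplicationResult:
    """Single-linkage clustering of bins over pairwise identity edges.

    An edge joins two bins when identity >= ``derep_identity`` and aligned
    fraction >= ``derep_aligned_frac``.  Each cluster's representative is
    its most complete bin (ties: lower contamination, then bin id).
    """
    thr = thresholds or Thresholds()
    parent = {b.bin_id: b.bin_id for b in bins}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for pair, (identity, aligned_frac) in identities.items():
        a, b = sorted(pair)
        if a not in parent or b not in parent:
            continue
        if identity >= thr.derep_identity and \
                aligned_frac >= thr.derep_aligned_frac:
            parent[find(a)] = find(b)

    groups: dict = {}
    for b in bins:
        groups.setdefault(find(b.bin_id), set()).add(b.bin_id)
    by_id = {b.bin_id: b for b in bins}

    def rep_key(bin_id):
        b = by_id[bin_id]
        return (-(b.completeness if b.completeness is not None else 0.0),
                b.contamination if b.contamination is not None else 100.0,
                bin_id)

    clusters = [frozenset(g) for g in groups.values()]
    clusters.sort(key=lambda c: min(c))
    representative = {c: min(c, key=rep_key) for c in clusters}
    return DereplicationResult(clusters=clusters, representative=representative)


def dereplicate_from_scaffolds(bins: Sequence[GenomeBin],
                               scaffold_seqs: Mapping[str, str],
                               thresholds: Optional[Thresholds] = None
                               ) -> DereplicationResult:
    """Compute all pairwise identities from scaffold sequences, then cluster."""
    seqs_by_bin = {
        b.bin_id: {s: scaffold_seqs[s] for s in sorted(b.scaffold_ids)
                   if s in scaffold_seqs}
        for b in bins}
    identities = {}
    for a, b in itertools.combinations(sorted(seqs_by_bin), 2):
        identities[frozenset((a, b))] = pairwise_identity(
            seqs_by_bin[a], seqs_by_bin[b])
    return dereplicate(bins, identities, thresholds)


# ---------------------------------------------------------------------------
# rpS3 accounting
# ---------------------------------------------------------------------------

def cluster_rps3(rps3_proteins: Mapping[str, str],
                 thresholds: Optional[Thresholds] = None) -> list:
    """Greedy centroid clustering of rpS3 sequences at high identity.

    Sequences are sorted longest-first (ties by id); each seeds a cluster
    unless it matches an existing centroid at >= ``rps3_cluster_identity``
    global amino-acid identity.  Returns a list of (centroid_id, member_ids)
    with the centroid first in members.
    """
    thr = thresholds or Thresholds()
    order = sorted(rps3_proteins, key=lambda k: (-len(rps3_proteins[k]), k))
    clusters: list = []
    for seq_id in order:
        seq = rps3_proteins[seq_id]
        placed = False
        for centroid_id, members in clusters:
            if global_identity(seq, rps3_proteins[centroid_id]) >= \
                    thr.rps3_cluster_identity:
                members.append(seq_id)
                placed = True
                break
        if not placed:
            clusters.append((seq_id, [seq_id]))
    return clusters


def rank_abundance(rps3_clusters: Sequence[Tuple[str, list]],
                   scaffold_of: Mapping[str, str],
                   coverage: pd.DataFrame,
                   bins: Mapping[str, Set[str]],
                   thresholds: Optional[Thresholds] = None,
                   top_k: int = 50) -> Tuple[pd.DataFrame, dict]:
    """Rank unique organisms (rpS3 clusters) by relative scaffold depth.

    Each cluster is represented by its centroid's scaffold; relative
    abundance is that scaffold's mean depth across samples divided by the
    total over all cluster representatives, computed per sample and averaged.
    The summary reports how many of the ``top_k`` most abundant organisms
    are in a bin, and — among unbinned organisms — the fraction rarer than
    ``rare_abundance_frac`` (the "missed organisms are rare" accounting).
    """
    thr = thresholds or Thresholds()
    binned_scaffolds = {s for members in bins.values() for s in members}
    rep_scaffold = {centroid: scaffold_of[centroid]
                    for centroid, _ in rps3_clusters}
    depth = coverage.loc[[rep_scaffold[c] for c, _ in rps3_clusters]]
    totals = depth.sum(axis=0)
    if float(totals.sum()) == 0.0:
        raise ValueError("all rpS3 scaffold depths are zero")
    rel = depth.div(totals.replace(0.0, np.nan), axis=1).fillna(0.0)
    mean_rel = rel.mean(axis=1)
    rows = []
    for (centroid, members) in rps3_clusters:
        scaffold = rep_scaffold[centroid]
        rows.append({
            "organism": centroid,
            "scaffold_id": scaffold,
            "n_members": len(members),
            "relative_abundance": float(mean_rel[scaffold]),
            "binned": scaffold in binned_scaffolds,
        })
    table = pd.DataFrame(rows).sort_values(
        ["relative_abundance", "organism"], ascending=[False, True]
    ).reset_index(drop=True)
    table.index = table.index + 1
    table.index.name = "rank"
    k = min(top_k, len(table))
    unbinned = table[~table["binned"]]
    summary = {
        "n_organisms": int(len(table)),
        "top_k": int(k),
        "top_k_binned": int(table.head(k)["binned"].sum()),
        "n_unbinned": int(len(unbinned)),
        "frac_unbinned_below_rare": (
            float((unbinned["relative_abundance"]
                   < thr.rare_abundance_frac).mean())
            if len(unbinned) else None),
    }
    return table, summary


def relative_abundance(bins: Sequence[GenomeBin],
                       scaffold_lengths: Mapping[str, int],
                       coverage: pd.DataFrame) -> pd.DataFrame:
    """Per-sample bin abundances from length-weighted mean scaffold depth.

    Columns (samples) are normalized to sum to 1 over bins, so doubling all
    depths in a sample leaves the table unchanged.
    """
    rows = {}
    for b in bins:
        scaffolds = sorted(b.scaffold_ids)
        lengths = np.array([scaffold_lengths[s] for s in scaffolds], float)
        if lengths.sum() == 0:
            raise ValueError(f"bin {b.bin_id}: zero total scaffold length")
        depths = coverage.loc[scaffolds]
        rows[b.bin_id] = (depths.mul(lengths, axis=0).sum(axis=0)
                          / lengths.sum())
    # normalize over sorted rows so bin input order cannot perturb sums
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "bin_id"
    totals = table.sum(axis=0)
    return table.div(totals.replace(0.0, np.nan), axis=1).fillna(0.0)


def abundance_correlation(abundance: pd.DataFrame,
                          thresholds: Optional[Thresholds] = None
                          ) -> pd.DataFrame:
    """Spearman abundance correlations between comparably abundant genomes.

    Only genome pairs whose mean abundances are within ``cooccur_ratio``
    fold of each other are tested (pairs at wildly different scales are not
    meaningfully comparable).  One interpretation of a ratio-thresholded
    co-occurrence screen; results are exploratory.
    """
    thr = thresholds or Thresholds()
    means = abundance.mean(axis=1)
    rows = []
    for a, b in itertools.combinations(sorted(abundance.index), 2):
        ma, mb = float(means[a]), float(means[b])
        if ma == 0 or mb == 0:
            continue
        ratio = max(ma, mb) / min(ma, mb)
        if ratio > thr.cooccur_ratio:
            continue
        rho, p = stats.spearmanr(abundance.loc[a], abundance.loc[b])
        rows.append({"bin_a": a, "bin_b": b, "ratio": ratio,
                     "spearman_rho": float(rho), "p_value": float(p)})
    return pd.DataFrame(rows,
                        columns=["bin_a", "bin_b", "ratio", "spearman_rho",
                                 "p_value"])


# ---------------------------------------------------------------------------
# alignment preparation
# ---------------------------------------------------------------------------

def trim_concatenated_alignment(blocks: Mapping[str, Mapping[str, str]],
                                thresholds: Optional[Thresholds] = None
                                ) -> Tuple[dict, set, set]:
    """Gap-trim per-gene alignment blocks, concatenate, and filter taxa.

    ``blocks`` maps gene name -> {taxon: aligned sequence}; taxa absent from
    a block are filled with gaps.  Three passes, never iterated:

    1. within each block, delete columns whose gap fraction (over the full
       taxon set) exceeds ``gap_col_max_frac``;
    2. concatenate blocks;
    3. drop taxa whose non-gap fraction is below ``seq_min_aligned_frac``.

    Returns ``(alignment, dropped_taxa, tree_eligible_taxa)`` where
    tree-eligible taxa have at least ``tree_min_positions`` non-gap columns.
    """
    thr = thresholds or Thresholds()
    taxa = sorted({t for block in blocks.values() for t in block})
    if not taxa:
        return {}, set(), set()

    pieces = {t: [] for t in taxa}
    for gene in sorted(blocks):
        block = blocks[gene]
        lengths = {len(s) for s in block.values()}
        if len(lengths) > 1:
            raise ValueError(f"block {gene}: unequal sequence lengths")
        width = lengths.pop() if lengths else 0
        mat = np.array([list(block.get(t, "-" * width)) for t in taxa])
        if width:
            gap_frac = np.isin(mat, list(GAP_CHARS)).mean(axis=0)
            mat = mat[:, gap_frac <= thr.gap_col_max_frac]
        for i, t in enumerate(taxa):
            pieces[t].append("".join(mat[i]))

    concatenated = {t: "".join(pieces[t]) for t in taxa}
    total = len(next(iter(concatenated.values())))
    nongap = {t: sum(1 for ch in seq if ch not in GAP_CHARS)
              for t, seq in concatenated.items()}
    if total == 0:
        return {t: "" for t in taxa}, set(), set()
    dropped = {t for t in taxa if nongap[t] / total < thr.seq_min_aligned_frac}
    alignment = {t: concatenated[t] for t in taxa if t not in dropped}
    tree_eligible = {t for t in alignment
                     if nongap[t] >= thr.tree_min_positions}
    return alignment, dropped, tree_eligible
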