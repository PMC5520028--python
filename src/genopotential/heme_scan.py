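"""CXXCH heme-binding motif scanning and multiheme-cytochrome calling.

A c-type cytochrome attaches heme at the CXXCH pattern (cysteine, two
arbitrary residues, cysteine, histidine).  Proteins carrying many such
motifs — multiheme cytochromes (MHCs) — are a hallmark of dissimilatory
metal reducers, so genomes rich in MHCs are flagged as putative iron
reducers.  Overlapping motif windows are all counted: heme-binding sites
tile densely in real cytochromes and overlap counting is the deterministic
reading.  The ambiguity code ``X`` (and an internal stop ``*``) fails the
match at every motif position, so ambiguous residues never inflate counts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Tuple

from .core_model import GenomeBin, Thresholds

logger = logging.getLogger("genopotential")

# C and H positions literal; the two middle positions may be any residue
# except X or * (including C and H themselves).  Lookahead -> overlaps count.
_CXXCH = re.compile(r"(?=C[^X*][^X*]CH)")


@dataclass
class MHCRecord:
    gene_id: str
    motif_count: int
    motif_starts: tuple  # 1-based window start positions, strictly increasing
    is_mhc: bool


@dataclass
class IronPrediction:
    bin_id: str
    n_mhcs: int
    max_motifs_single_protein: int
    predicted_iron_reducer: bool


def count_cxxch(protein: str) -> Tuple[int, list]:
    """Count CXXCH windows in an uppercased protein.

    Returns ``(count, positions)`` with 1-based window start positions.
    Every qualifying window is counted, overlapping ones included; the empty
    string yields ``(0, [])``.
    """
    positions = [m.start() + 1 for m in _CXXCH.finditer(protein)]
    return len(positions), positions


def call_mhcs(proteome: Mapping[str, str],
              thresholds: Optional[Thresholds] = None) -> list:
    """Scan every protein and label MHCs (>= ``mhc_min_motifs`` motifs)."""
    thr = thresholds or Thresholds()
    if not proteome:
        raise ValueError("empty proteome")
    records = []
    for gene_id, protein in proteome.items():
        count, positions = count_cxxch(protein)
        records.append(MHCRecord(gene_id=gene_id, motif_count=count,
                                 motif_starts=tuple(positions),
                                 is_mhc=count >= thr.mhc_min_motifs))
    return records


def predict_iron_reducers(bins: Iterable[GenomeBin],
                          mhcs: Iterable[MHCRecord],
                          gene_bins: Mapping[str, str],
                          thresholds: Optional[Thresholds] = None) -> list:
    """Flag bins holding >= ``iron_min_mhcs`` MHC proteins as iron reducers.

    ``gene_bins`` maps gene ids to bin ids (genes absent from the map are
    unbinned and ignored).  Bins with no scanned protein get an all-zero row.
    """
    thr = thresholds or Thresholds()
    n_mhc: dict = {}
    max_motifs: dict = {}
    for rec in mhcs:
        bin_id = gene_bins.get(rec.gene_id)
        if bin_id is None:
            continue
        if rec.is_mhc:
            n_mhc[bin_id] = n_mhc.get(bin_id, 0) + 1
        if rec.motif_count > max_motifs.get(bin_id, 0):
            max_motifs[bin_id] = rec.motif_count
    return [IronPrediction(
        bin_id=b.bin_id,
        n_mhcs=n_mhc.get(b.bin_id, 0),
        max_motifs_single_protein=max_motifs.get(b.bin_id, 0),
        predicted_iron_reducer=n_mhc.get(b.bin_id, 0) >= thr.iron_min_mhcs)
        for b in bins]


def evaluate_predictor(predictions: Iterable[IronPrediction],
                       labels: Mapping[str, bool]
                       ) -> Tuple[float, Optional[float]]:
    """Reference-set validation of the MHC-count iron-reduction predictor.

    Returns ``(prevalence, precision)``: the fraction of genomes flagged,
    and among flagged genomes with a known label, the fraction labelled as
    true iron reducers.  Flagged genomes without a label are excluded from
    precision with a warning; precision is ``None`` when no flagged genome
    is labelled.
    """
    predictions = list(predictions)
    if not predictions:
        raise ValueError("no predictions to evaluate")
    flagged = [p for p in predictions if p.predicted_iron_reducer]
    prevalence = len(flagged) / len(predictions)
    labelled = [p for p in flagged if p.bin_id in labels]
    if len(labelled) < len(flagged):
        logger.warning("%d flagged genomes lack labels; excluded from "
                       "precision", len(flagged) - len(labelled))
    if not labelled:
        return prevalence, None
    true_pos = sum(1 for p in labelled if labels[p.bin_id])
    return prevalence, true_pos / len(labelled)
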