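"""Hydrogenase classification from profile hits and operon context.

Catalytic subunits are typed to a cofactor class ([NiFe], [FeFe], [Fe]) and
group from their best profile hit.  [FeFe] Group A cannot be split by
sequence alone: Group A3 enzymes electron-bifurcate and require two extra
subunits encoded immediately downstream — hydB (a diaphorase ortholog with
multiple [4Fe-4S] clusters) and hydC (a small [2Fe-2S] protein) — whereas
Group A1 enzymes are monomeric.  A Group A gene is therefore called A3 when
co-oriented hydB and hydC genes both occur within ``operon_window`` genes
downstream in the reading direction, A1 when a full window shows no such
pair, and A_unresolved when the scaffold ends before the window completes
with the evidence still incomplete.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .core_model import GeneCall, GenomeBin, ProfileHit, Thresholds

logger = logging.getLogger("genopotential")

#: catalytic-subunit profile label -> (cofactor, group)
PROFILE_GROUPS = {
    "NiFe_G1": ("NiFe", "1"),
    "NiFe_G2": ("NiFe", "2"),
    "NiFe_G3": ("NiFe", "3"),
    "NiFe_G4": ("NiFe", "4"),
    "FeFe_GA": ("FeFe", "A"),
    "FeFe_GB": ("FeFe", "B"),
    "FeFe_GC": ("FeFe", "C"),
    "Fe_hmd": ("Fe", "hmd"),
}

#: accessory-subunit profile labels used for Group A resolution
ACCESSORY_ROLES = {"hydB": "hydB", "hydC": "hydC"}

#: profile labels counted as Rnf-complex markers
RNF_PROFILES = frozenset({"rnfA", "rnfB", "rnfC", "rnfD", "rnfE", "rnfG"})

# sequence-signature fallback for fixture-only runs without hydB/hydC hits
_4FE4S = re.compile(r"(?=C..C..C)")
_2FE2S = re.compile(r"C..G.C")


@dataclass
class HydrogenaseCall:
    gene_id: str
    cofactor: str            # NiFe | FeFe | Fe
    group: str               # 1-4 | A | B | C | hmd
    subgroup: str            # A1 | A3 | A_unresolved | n/a
    evidence: tuple = ()     # ((neighbor gene_id, role), ...)
    best_hit: Optional[ProfileHit] = None
    ambiguous: bool = False

    @property
    def label(self) -> str:
        if self.group == "A":
            return self.subgroup
        if self.cofactor == "NiFe":
            return f"NiFe_{self.group}"
        if self.cofactor == "Fe":
            return "Fe"
        return self.group


@dataclass
class HydrogenaseSummary:
    """Per-bin hydrogenase count matrix plus derived booleans."""

    counts: dict                      # bin_id -> Counter of call labels
    has_rnf: dict = field(default_factory=dict)

    def has_a1(self, bin_id: str) -> bool:
        return self.counts.get(bin_id, Counter())["A1"] > 0

    def has_a3(self, bin_id: str) -> bool:
        return self.counts.get(bin_id, Counter())["A3"] > 0

    has_bifurcating = has_a3

    def has_b(self, bin_id: str) -> bool:
        return self.counts.get(bin_id, Counter())["B"] > 0

    def total(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        labels = sorted({l for c in self.counts.values() for l in c})
        rows = {b: {l: c[l] for l in labels} for b, c in self.counts.items()}
        df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
        df.index.name = "bin_id"
        df["has_rnf"] = [bool(self.has_rnf.get(b, False)) for b in df.index]
        return df.sort_index()


def assign_group(hits_for_gene: Iterable[ProfileHit]
                 ) -> Optional[Tuple[str, str, bool, ProfileHit]]:
    """Type one gene from its (cutoff-filtered) catalytic-profile hits.

    Returns ``(cofactor, group, ambiguous, best_hit)`` or ``None`` when the
    gene has no hydrogenase-family hit.  The best bit score wins; exact ties
    are broken by lexicographic profile name and flagged ambiguous.
    """
    family_hits = [h for h in hits_for_gene if h.profile in PROFILE_GROUPS]
    if not family_hits:
        return None
    best_score = max(h.bit_score for h in family_hits)
    top = sorted((h for h in family_hits if h.bit_score == best_score),
                 key=lambda h: h.profile)
    best = top[0]
    ambiguous = len({h.profile for h in top}) > 1
    cofactor, group = PROFILE_GROUPS[best.profile]
    return cofactor, group, ambiguous, best


def _neighbor_roles(gene: GeneCall, roles_by_gene: Mapping[str, set],
                    use_sequence_heuristic: bool) -> set:
    roles = set(roles_by_gene.get(gene.gene_id, ()))
    if use_sequence_heuristic and not roles and gene.protein:
        if len(_4FE4S.findall(gene.protein)) >= 2:
            roles.add("hydB")
        if len(gene.protein) < 120 and _2FE2S.search(gene.protein):
            roles.add("hydC")
    return roles


def resolve_group_a(gene: GeneCall,
                    scaffold_genes: Sequence[GeneCall],
                    roles_by_gene: Mapping[str, set],
                    thresholds: Optional[Thresholds] = None,
                    use_sequence_heuristic: bool = False
                    ) -> Tuple[str, tuple]:
    """Split a [FeFe] Group A catalytic gene into A1 / A3 / A_unresolved.

    ``scaffold_genes`` are all genes of the gene's scaffold, sorted by
    ordinal; ``roles_by_gene`` maps gene ids to accessory roles seen in the
    hit table ({"hydB"}, {"hydC"}).  Only neighbors on the catalytic gene's
    strand count as evidence (operons are co-oriented).
    """
    thr = thresholds or Thresholds()
    ordered = sorted(scaffold_genes, key=lambda g: g.ordinal)
    idx = next((i for i, g in enumerate(ordered) if g.gene_id == gene.gene_id),
               None)
    if idx is None:
        raise ValueError(
            f"gene {gene.gene_id} not among genes of scaffold "
            f"{gene.scaffold_id}")
    if gene.strand == "+":
        window = ordered[idx + 1: idx + 1 + thr.operon_window]
    else:
        window = ordered[max(0, idx - thr.operon_window): idx][::-1]
    truncated = len(window) < thr.operon_window

    evidence = []
    found: set = set()
    for neighbor in window:
        if neighbor.strand != gene.strand:
            continue
        for role in _neighbor_roles(neighbor, roles_by_gene,
                                    use_sequence_heuristic):
            evidence.append((neighbor.gene_id, role))
            found.add(role)
    if {"hydB", "hydC"} <= found:
        return "A3", tuple(evidence)
    if truncated:
        return "A_unresolved", tuple(evidence)
    return "A1", tuple(evidence)


def classify_hydrogenases(calls: Sequence[GeneCall],
                          hits: Iterable[ProfileHit],
                          thresholds: Optional[Thresholds] = None,
                          use_sequence_heuristic: bool = False) -> list:
    """Type every gene with a hydrogenase-family hit; resolve Group A context.

    Output order follows (scaffold_id, ordinal), so identical inputs yield
    identical call lists regardless of the order genes were supplied in.
    """
    thr = thresholds or Thresholds()
    hits_by_gene: dict = {}
    roles_by_gene: dict = {}
    for h in hits:
        hits_by_gene.setdefault(h.gene_id, []).append(h)
        if h.profile in ACCESSORY_ROLES:
            roles_by_gene.setdefault(h.gene_id, set()).add(
                ACCESSORY_ROLES[h.profile])

    by_scaffold: dict = {}
    for c in calls:
        by_scaffold.setdefault(c.scaffold_id, []).append(c)
    for group in by_scaffold.values():
        group.sort(key=lambda g: g.ordinal)

    out = []
    for scaffold_id in sorted(by_scaffold):
        for gene in by_scaffold[scaffold_id]:
            assignment = assign_group(hits_by_gene.get(gene.gene_id, ()))
            if assignment is None:
                continue
            cofactor, group, ambiguous, best = assignment
            subgroup, evidence = "n/a", ()
            if (cofactor, group) == ("FeFe", "A"):
                subgroup, evidence = resolve_group_a(
                    gene, by_scaffold[scaffold_id], roles_by_gene, thr,
                    use_sequence_heuristic)
            out.append(HydrogenaseCall(
                gene_id=gene.gene_id, cofactor=cofactor, group=group,
                subgroup=subgroup, evidence=evidence, best_hit=best,
                ambiguous=ambiguous))
    return out


def summarize_hydrogenases(bins: Iterable[GenomeBin],
                           calls: Iterable[HydrogenaseCall],
                           hits: Iterable[ProfileHit],
                           gene_bins: Mapping[str, str]
                           ) -> HydrogenaseSummary:
    """Per-bin count matrix keyed by call label, plus Rnf presence.

    ``has_rnf`` is true for a bin holding at least one Rnf-complex marker
    hit; unbinned genes are ignored.
    """
    counts = {b.bin_id: Counter() for b in bins}
    has_rnf = {b: False for b in counts}
    for call in calls:
        bin_id = gene_bins.get(call.gene_id)
        if bin_id in counts:
            counts[bin_id][call.label] += 1
    for h in hits:
        if h.profile in RNF_PROFILES:
            bin_id = gene_bins.get(h.gene_id)
            if bin_id in has_rnf:
                has_rnf[bin_id] = True
    return HydrogenaseSummary(counts=counts, has_rnf=has_rnf)


def cooccurrence_stats(summary: HydrogenaseSummary
                       ) -> Tuple[Optional[float], Optional[float],
                                  Optional[float]]:
    """Genome-level co-occurrence fractions.

    Returns ``(frac_A1_with_A3, frac_bifurcating_with_rnf, frac_B_with_A3)``;
    each is |bins with both| / |bins with the first|, or ``None`` when no
    bin has the first feature.
    """
    bins = list(summary.counts)
    if not bins:
        raise ValueError("empty hydrogenase summary")

    def frac(first, second):
        with_first = [b for b in bins if first(b)]
        if not with_first:
            return None
        return sum(1 for b in with_first if second(b)) / len(with_first)

    return (
        frac(summary.has_a1, summary.has_a3),
        frac(summary.has_a3, lambda b: summary.has_rnf.get(b, False)),
        frac(summary.has_b, summary.has_a3),
    )
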