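"""Rule-based biogeochemical pathway profiling of genome bins.

A pathway rule is a conjunction of clauses, each clause a disjunction of
interchangeable marker genes (e.g. denitrification to N2 requires
{narG|napA} AND {nirK|nirS} AND {norB} AND {nosZ}).  A bin's status is

* ``complete`` — every clause satisfied,
* ``absent``   — no (positive) clause satisfied,
* ``partial``  — anything in between.

A clause may be negated: partial nitrification, for instance, is defined by
the presence of hydroxylamine dehydrogenase together with the *absence* of
ammonia monooxygenase.  A negated clause is satisfied when none of its genes
is present; the absent/complete poles are anchored on positive clauses so an
empty genome is ``absent``, never ``partial``.

Fermentation and complex-carbon degradation are not all-or-nothing pathways
and are profiled as gene counts bucketed into none/low/high tiers instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .core_model import GenomeBin, Thresholds
from .hydrogenase_typing import HydrogenaseSummary

logger = logging.getLogger("genopotential")

STATUS_COMPLETE = "complete"
STATUS_PARTIAL = "partial"
STATUS_ABSENT = "absent"


@dataclass(frozen=True)
class Clause:
    alternatives: frozenset
    negated: bool = False

    def satisfied(self, genes: Set[str]) -> bool:
        present = bool(self.alternatives & genes)
        return not present if self.negated else present


@dataclass(frozen=True)
class PathwayRule:
    pathway: str
    category: str
    clauses: tuple = ()
    mode: str = "clauses"          # "clauses" | "count"
    count_genes: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.mode == "clauses":
            if not self.clauses:
                raise ValueError(f"rule {self.pathway}: no clauses")
            if all(c.negated for c in self.clauses):
                raise ValueError(
                    f"rule {self.pathway}: needs at least one positive clause")
            for c in self.clauses:
                if not c.alternatives:
                    raise ValueError(f"rule {self.pathway}: empty clause")
        elif self.mode == "count":
            if not self.count_genes:
                raise ValueError(f"rule {self.pathway}: empty count vocabulary")
        else:
            raise ValueError(f"rule {self.pathway}: unknown mode {self.mode}")

    def vocabulary(self) -> frozenset:
        if self.mode == "count":
            return self.count_genes
        return frozenset(g for c in self.clauses for g in c.alternatives)


@dataclass
class PathwayCall:
    bin_id: str
    pathway: str
    status: str
    satisfied_clauses: int
    genes_found: tuple


def load_rulebook(path=None) -> list:
    """Load pathway rules from a rulebook TSV (default: the shipped rulebook).

    Columns: pathway, category, mode, clause_index, alternatives
    ('|'-separated), negated (0/1).
    """
    if path is None:
        with resources.files("genopotential.data").joinpath(
                "pathway_rules.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    rules = []
    for (pathway, category, mode), grp in df.groupby(
            ["pathway", "category", "mode"], sort=False):
        if mode == "count":
            genes = frozenset(g for alts in grp["alternatives"]
                              for g in alts.split("|"))
            rules.append(PathwayRule(pathway=pathway, category=category,
                                     mode="count", count_genes=genes))
        else:
            grp = grp.sort_values("clause_index", key=lambda s: s.astype(int))
            clauses = tuple(
                Clause(frozenset(row.alternatives.split("|")),
                       negated=row.negated == "1")
                for row in grp.itertuples())
            rules.append(PathwayRule(pathway=pathway, category=category,
                                     clauses=clauses))
    return rules


def evaluate_pathway(bin_genes: Set[str], rule: PathwayRule,
                     bin_id: str = "") -> PathwayCall:
    """Call one clause-mode rule on a bin's set of marker-gene labels."""
    if rule.mode != "clauses":
        raise ValueError(f"rule {rule.pathway} is count-mode; use count_genes")
    satisfied = [c for c in rule.clauses if c.satisfied(bin_genes)]
    positive = [c for c in rule.clauses if not c.negated]
    pos_satisfied = [c for c in satisfied if not c.negated]
    if len(satisfied) == len(rule.clauses) and pos_satisfied:
        status = STATUS_COMPLETE
    elif not pos_satisfied:
        status = STATUS_ABSENT
    else:
        status = STATUS_PARTIAL
    genes_found = tuple(sorted(
        g for c in positive for g in (c.alternatives & bin_genes)))
    return PathwayCall(bin_id=bin_id, pathway=rule.pathway, status=status,
                       satisfied_clauses=len(satisfied),
                       genes_found=genes_found)


def count_pathway_genes(bin_genes: Set[str], rule: PathwayRule) -> int:
    """Number of a count-mode rule's vocabulary genes present in the bin."""
    if rule.mode != "count":
        raise ValueError(f"rule {rule.pathway} is clause-mode")
    return len(rule.count_genes & bin_genes)


def call_pathways(bin_genes_by_bin: Mapping[str, Set[str]],
                  rules: Optional[Sequence[PathwayRule]] = None) -> list:
    """Evaluate every clause-mode rule on every bin."""
    rules = list(rules) if rules is not None else load_rulebook()
    calls = []
    for bin_id in sorted(bin_genes_by_bin):
        genes = set(bin_genes_by_bin[bin_id])
        for rule in rules:
            if rule.mode == "clauses":
                calls.append(evaluate_pathway(genes, rule, bin_id=bin_id))
    return calls


def _tier(count: int, high_cut: float) -> str:
    if count == 0:
        return "none"
    return "high" if count > high_cut else "low"


def build_profile_matrix(bins: Iterable[GenomeBin],
                         pathway_calls: Iterable[PathwayCall],
                         hydrogenase_summary: Optional[HydrogenaseSummary],
                         abundance: pd.DataFrame,
                         bin_genes_by_bin: Optional[Mapping[str, Set[str]]] = None,
                         rules: Optional[Sequence[PathwayRule]] = None,
                         thresholds: Optional[Thresholds] = None
                         ) -> pd.DataFrame:
    """Bin x feature matrix of metabolic potential for the abundant community.

    Rows are bins whose mean relative abundance across samples exceeds
    ``rare_abundance_frac``, ordered by descending mean abundance.  Columns
    are pathway statuses, count-rule tiers (terciles of the non-zero counts),
    hydrogenase call counts and the mean abundance itself.
    """
    thr = thresholds or Thresholds()
    bins = list(bins)
    mean_abund = abundance.mean(axis=1) if abundance.size else pd.Series(dtype=float)
    if abundance.size and float(abundance.values.sum()) == 0.0:
        logger.warning("all-zero abundance table; profile matrix is empty")
    keep = [b.bin_id for b in bins
            if float(mean_abund.get(b.bin_id, 0.0)) > thr.rare_abundance_frac]
    keep.sort(key=lambda b: (-float(mean_abund[b]), b))

    data: dict = {b: {"mean_abundance": float(mean_abund[b])} for b in keep}
    for call in pathway_calls:
        if call.bin_id in data:
            data[call.bin_id][call.pathway] = call.status

    if rules is None:
        rules = load_rulebook()
    count_rules = [r for r in rules if r.mode == "count"]
    if count_rules and bin_genes_by_bin is not None:
        for rule in count_rules:
            counts = {b: count_pathway_genes(set(bin_genes_by_bin.get(b, ())),
                                             rule) for b in keep}
            nonzero = [c for c in counts.values() if c > 0]
            high_cut = float(np.quantile(nonzero, 2 / 3)) if nonzero else 0.0
            for b in keep:
                data[b][f"{rule.pathway}_genes"] = counts[b]
                data[b][f"{rule.pathway}_tier"] = _tier(counts[b], high_cut)

    if hydrogenase_summary is not None:
        labels = sorted({l for c in hydrogenase_summary.counts.values()
                         for l in c})
        for b in keep:
            counter = hydrogenase_summary.counts.get(b, {})
            for label in labels:
                data[b][f"hyd_{label}"] = int(counter.get(label, 0))
            data[b]["has_rnf"] = bool(
                hydrogenase_summary.has_rnf.get(b, False))

    df = pd.DataFrame.from_dict(data, orient="index")
    df.index.name = "bin_id"
    return df.loc[keep] if keep else df
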