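"""The in-silico matrisome construction cascade.

The cascade mirrors the standard in-silico matrisome workflow: a positive
domain screen over the whole proteome, curation down to proteins carrying a
bona fide ECM signature domain (with exact-duplicate collapse), first-match
category assignment under exclusion-domain barring and signal/membrane gating,
venom flagging against a toxin-database BLAST report, and intersection with a
mass-spectrometry-detected protein list.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io import (DomainHit, LocalizationPrediction, ProteinRecord,
                 SignalPrediction)
from .rules import DomainRuleSet

__all__ = [
    "MatrisomeAssignment",
    "ClassificationSummary",
    "ExclusionRecord",
    "screen_candidates",
    "curate",
    "assign_division",
    "flag_venom",
    "classify_proteome",
    "intersect_with_evidence",
    "write_assignments",
]

NON_ECM = "non-ECM"


@dataclass(frozen=True)
class MatrisomeAssignment:
    protein_id: str
    division: str  # core | associated | adhesome | other | non-ECM
    category: Optional[str]
    evidence: tuple[tuple[str, str], ...] = ()  # (accession, rule) pairs
    has_signal: bool = False
    membrane: bool = False
    venom_candidate: bool = False
    cnidarian_specific: bool = False

    def __post_init__(self) -> None:
        if (self.division == NON_ECM) != (self.category is None):
            raise ValueError("division is non-ECM iff category is none")
        if self.division != NON_ECM and not self.evidence:
            raise ValueError("ECM assignments must carry evidence")


@dataclass(frozen=True)
class ExclusionRecord:
    protein_id: str
    reason: str
    detail: str = ""


@dataclass
class ClassificationSummary:
    """Counting summary of one classification run.

    ``n_matrisome`` is always core + associated; division counts partition the
    curated set.
    """

    n_screened: int
    n_candidates: int
    n_curated: int
    per_division: dict[str, int] = field(default_factory=dict)
    per_category: dict[str, int] = field(default_factory=dict)

    @property
    def n_matrisome(self) -> int:
        return matrisome_total(self.per_division.get("core", 0),
                               self.per_division.get("associated", 0))

    def to_json(self, path: str | Path) -> None:
        doc = {
            "n_screened": self.n_screened,
            "n_candidates": self.n_candidates,
            "n_curated": self.n_curated,
            "n_matrisome": self.n_matrisome,
            "per_division": self.per_division,
            "per_category": self.per_category,
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def matrisome_total(n_core: int, n_associated: int) -> int:
    """Matrisome size = core + associated divisions (the headline identity)."""
    return n_core + n_associated


def _hits_by_protein(hits: Iterable[DomainHit]) -> dict[str, list[DomainHit]]:
    by: dict[str, list[DomainHit]] = defaultdict(list)
    for h in hits:
        by[h.protein_id].append(h)
    return by


def screen_candidates(
    hits: Iterable[DomainHit], rules: DomainRuleSet
) -> set[str]:
    """Positive screen: proteins with >= 1 accession in the inclusion union."""
    positive = rules.positive_screen
    if not positive:
        raise ValueError("rule set has an empty positive screen")
    return {h.protein_id for h in hits if h.domain_id in positive}


def curate(
    candidates: set[str],
    hits: Iterable[DomainHit],
    sequences: Sequence[ProteinRecord],
    rules: DomainRuleSet,
    signal: Optional[dict[str, SignalPrediction]] = None,
) -> tuple[set[str], list[ExclusionRecord]]:
    """Curation: keep candidates with a bona fide ECM domain; collapse exact
    duplicate sequences to the lexicographically lowest id.

    Returns the curated id set and an exclusion report listing every removal
    with its reason.
    """
    by_protein = _hits_by_protein(hits)
    report: list[ExclusionRecord] = []
    kept: set[str] = set()
    for pid in sorted(candidates):
        accs = {h.domain_id for h in by_protein.get(pid, [])}
        if not accs & rules.bona_fide:
            report.append(ExclusionRecord(pid, "no_bona_fide_domain"))
            continue
        kept.add(pid)

    # exact-duplicate collapse among the retained set
    seq_of = {r.protein_id: r.sequence for r in sequences if r.sequence}
    groups: dict[str, list[str]] = defaultdict(list)
    for pid in sorted(kept):
        if pid in seq_of:
            groups[seq_of[pid]].append(pid)
    for seq, pids in groups.items():
        if len(pids) > 1:
            representative = min(pids)
            for pid in pids:
                if pid != representative:
                    kept.discard(pid)
                    report.append(ExclusionRecord(
                        pid, "duplicate_sequence", f"kept {representative}"))
    return kept, report


def assign_division(
    protein_id: str,
    hits: Iterable[DomainHit],
    signal: Optional[dict[str, SignalPrediction]],
    localization: Optional[dict[str, LocalizationPrediction]],
    rules: DomainRuleSet,
    venom_candidate: bool = False,
    cnidarian_specific: bool = False,
) -> MatrisomeAssignment:
    """First-match category assignment with exclusion-domain barring.

    Order of evaluation: (1) any category whose exclusion domains match is
    barred for this protein; (2) the first unbarred category (rule-set order)
    whose inclusion domains match and whose signal/membrane requirements hold
    is assigned; (3) the category fixes the division; (4) with no category,
    a bona fide ECM domain demotes to other/other_ecm, otherwise non-ECM.
    """
    protein_hits = [h for h in hits if h.protein_id == protein_id]
    if not protein_hits:
        raise KeyError(f"{protein_id}: no domain hits on record")
    accs = {h.domain_id for h in protein_hits}
    has_signal = bool(signal and protein_id in signal
                      and signal[protein_id].has_signal)
    membrane = bool(localization and protein_id in localization
                    and localization[protein_id].membrane_flag)

    for cat in rules.categories:
        if accs & cat.exclusion:
            continue  # barred
        matched = accs & cat.inclusion
        if not matched:
            continue
        if cat.requires_signal and not has_signal:
            continue
        if cat.membrane == "required" and not membrane:
            continue
        if cat.membrane == "forbidden" and membrane:
            continue
        evidence = tuple(sorted((a, f"inclusion:{cat.name}") for a in matched))
        return MatrisomeAssignment(
            protein_id, cat.division, cat.name, evidence,
            has_signal=has_signal, membrane=membrane,
            venom_candidate=venom_candidate,
            cnidarian_specific=cnidarian_specific,
        )

    bona = accs & rules.bona_fide
    if bona:
        evidence = tuple(sorted((a, "bona_fide_fallback") for a in bona))
        return MatrisomeAssignment(
            protein_id, "other", "other_ecm", evidence,
            has_signal=has_signal, membrane=membrane,
            venom_candidate=venom_candidate,
            cnidarian_specific=cnidarian_specific,
        )
    return MatrisomeAssignment(
        protein_id, NON_ECM, None, (),
        has_signal=has_signal, membrane=membrane,
        venom_candidate=venom_candidate,
        cnidarian_specific=cnidarian_specific,
    )


def flag_venom(
    protein_id: str,
    toxdb_hits: Iterable[tuple[str, float]],
    threshold: float = 1e-3,
) -> bool:
    """Flag a protein as a putative venom from toxin-database BLAST hits.

    True iff the best (smallest) e-value is at or below ``threshold``
    (default 1e-3).  No hits -> False.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    best = None
    for _subject, evalue in toxdb_hits:
        if evalue < 0:
            raise ValueError(f"{protein_id}: negative e-value {evalue}")
        if best is None or evalue < best:
            best = evalue
    return best is not None and best <= threshold


def classify_proteome(
    proteome: Sequence[ProteinRecord],
    hits: Sequence[DomainHit],
    signal: Optional[dict[str, SignalPrediction]],
    localization: Optional[dict[str, LocalizationPrediction]],
    rules: DomainRuleSet,
    toxdb_hits: Optional[dict[str, list[tuple[str, float]]]] = None,
    venom_threshold: float = 1e-3,
    cnidarian_specific_ids: Optional[set[str]] = None,
) -> tuple[list[MatrisomeAssignment], ClassificationSummary, list[ExclusionRecord]]:
    """The full cascade: screen -> curate -> assign, with summary counting.

    Assignments are returned sorted by protein id; the summary's division
    counts partition the curated set and ``n_matrisome`` is core + associated.
    """
    candidates = screen_candidates(hits, rules) if hits else set()
    curated, report = curate(candidates, hits, proteome, rules, signal)
    by_protein = _hits_by_protein(hits)
    assignments = []
    for pid in sorted(curated):
        venom = flag_venom(pid, (toxdb_hits or {}).get(pid, []), venom_threshold)
        assignments.append(assign_division(
            pid, by_protein[pid], signal, localization, rules,
            venom_candidate=venom,
            cnidarian_specific=pid in (cnidarian_specific_ids or set()),
        ))
    per_division = Counter(a.division for a in assignments)
    per_category = Counter(a.category for a in assignments if a.category)
    summary = ClassificationSummary(
        n_screened=len(proteome),
        n_candidates=len(candidates),
        n_curated=len(curated),
        per_division=dict(per_division),
        per_category=dict(per_category),
    )
    return assignments, summary, report


def intersect_with_evidence(
    assignments: Sequence[MatrisomeAssignment], detected_ids: set[str]
) -> dict[str, int]:
    """Confirm curated proteins against a mass-spectrometry-detected id set.

    Returns per-division confirmed counts, ``total`` (curated ∩ detected) and
    ``detected_not_curated`` (candidate cellular contaminants in the isolate).
    """
    curated_ids = {a.protein_id for a in assignments}
    confirmed = curated_ids & detected_ids
    counts: dict[str, int] = {}
    for a in assignments:
        if a.protein_id in confirmed:
            counts[a.division] = counts.get(a.division, 0) + 1
    counts["total"] = len(confirmed)
    counts["detected_not_curated"] = len(detected_ids - curated_ids)
    return counts


def write_assignments(
    assignments: Sequence[MatrisomeAssignment], path: str | Path
) -> None:
    rows = [{
        "protein_id": a.protein_id,
        "division": a.division,
        "category": a.category or "",
        "evidence": ";".join(f"{acc}|{rule}" for acc, rule in a.evidence),
        "has_signal": a.has_signal,
        "membrane": a.membrane,
        "venom_candidate": a.venom_candidate,
        "cnidarian_specific": a.cnidarian_specific,
    } for a in assignments]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_exclusion_report(
    report: Sequence[ExclusionRecord], path: str | Path
) -> None:
    pd.DataFrame([{
        "protein_id": r.protein_id, "reason": r.reason, "detail": r.detail,
    } for r in report]).to_csv(path, sep="\t", index=False)
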