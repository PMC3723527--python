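"""Protein-level consequence prediction for detected splicing events.

Each event (a probe-set region with an inclusion/exclusion direction) is
mapped onto the annotated isoforms of its gene.  Isoforms are partitioned
into those containing the event region and those lacking it, and every
(with, without) pair is compared structurally through its CDS annotation.
The isoform favored in the test condition (the "with" isoform for inclusion
events, the "without" one for exclusion) is contrasted against the other:

* **NMD** - the favored isoform carries a premature termination codon,
  i.e. its stop lies more than ``nmd_nt`` (default 50) nucleotides upstream
  of its final exon-exon junction in spliced coordinates, while the other
  isoform does not.  Single-exon transcripts cannot have a PTC; isoforms
  whose CDS length is not a whole number of codons are flagged invalid and
  excluded from NMD evidence.
* **truncation** - the favored protein is at most half (``truncation_ratio``)
  the length of the other.
* **altN / altC** - the proteins differ at the N-terminus (C-terminus)
  while sharing the other end, anchored on the genomic coordinates of the
  CDS ends.  When both ends differ the call is {altN, altC}.
* **intron_retention** - the event region lies in an intron of the
  non-favored isoform and that whole intron is exonic in the favored one.
* **alt_coding** - both termini are shared but the internal CDS structure
  differs (in-frame inclusion/exclusion of coding sequence).

A single event may carry several consequences; the call is the union over
all isoform pairs, with per-pair evidence retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exprio import Interval, TranscriptModel

NMD = "NMD"
TRUNCATION = "truncation"
ALT_N = "altN"
ALT_C = "altC"
INTRON_RETENTION = "intron_retention"
ALT_CODING = "alt_coding"

CATEGORIES = (NMD, TRUNCATION, ALT_N, ALT_C, INTRON_RETENTION, ALT_CODING)


@dataclass(frozen=True)
class ConsequenceParams:
    """Tunable rule boundaries.

    ``nmd_nt``: strict ">" distance (nt) from stop to final junction for a
    PTC. ``truncation_ratio``: inclusive protein-length ratio at or below
    which truncation is called. ``min_overlap``: fraction of the event
    region that must be exonic for an isoform to count as containing it.
    """

    nmd_nt: int = 50
    truncation_ratio: float = 0.5
    min_overlap: float = 0.5


@dataclass(frozen=True)
class PtcStatus:
    has_ptc: bool
    distance_nt: int | None
    frame_valid: bool


@dataclass(frozen=True)
class PairEvidence:
    isoform_with: str
    isoform_without: str
    ptc_distance_nt: int | None
    protein_ratio: float | None
    labels: frozenset


@dataclass(frozen=True)
class ConsequenceCall:
    probeset_id: str
    gene_id: str
    direction: str
    consequences: frozenset
    evidence: tuple[PairEvidence, ...] = ()


def partition_isoforms(
    models: Sequence[TranscriptModel],
    region: Interval,
    min_overlap: float = 0.5,
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Split a gene's isoforms into (containing, lacking) the event region.

    Containment means >= ``min_overlap`` of the region is exonic in the
    isoform, so regions straddling an exon boundary are assigned by majority
    overlap.  A region exonic in no isoform yields ``([], models)`` and the
    downstream call carries no consequences.
    """
    with_, without = [], []
    for m in models:
        (with_ if m.contains_region(region, min_overlap) else without).append(m)
    return with_, without


def ptc_status(model: TranscriptModel, nmd_nt: int = 50) -> PtcStatus:
    """Premature-termination-codon status of one isoform.

    Distance is measured in spliced coordinates from the end of the stop
    codon to the final exon-exon junction; a stop more than ``nmd_nt``
    nucleotides upstream (strict inequality) marks the transcript as
    NMD-eligible.  Single-exon transcripts are never PTC-positive.
    """
    if not model.cds:
        raise ValueError(f"{model.transcript_id}: no CDS annotated")
    valid = model.frame_valid
    junction = model.final_junction_spliced
    if junction is None:
        return PtcStatus(False, None, valid)
    distance = junction - model.stop_spliced_end
    return PtcStatus(valid and distance > nmd_nt, distance, valid)


def _intron_retained(
    favored: TranscriptModel, other: TranscriptModel, region: Interval
) -> bool:
    s, e = region
    for ia, ib in other.introns:
        if ia <= s and e <= ib:
            return any(ea <= ia and ib <= eb for ea, eb in favored.exons)
    return False


def _pair_labels(
    w: TranscriptModel,
    wo: TranscriptModel,
    direction: str,
    region: Interval,
    params: ConsequenceParams,
) -> PairEvidence:
    favored, other = (w, wo) if direction == "inclusion" else (wo, w)
    labels = set()
    fav_ptc = ptc_status(favored, params.nmd_nt)
    oth_ptc = ptc_status(other, params.nmd_nt)
    if fav_ptc.has_ptc and not oth_ptc.has_ptc:
        labels.add(NMD)
    ratio = None
    if other.protein_length_aa > 0:
        ratio = favored.protein_length_aa / other.protein_length_aa
        if ratio <= params.truncation_ratio:
            labels.add(TRUNCATION)
    n_shared = w.cds_start_genomic == wo.cds_start_genomic
    c_shared = w.cds_end_genomic == wo.cds_end_genomic
    if not n_shared:
        labels.add(ALT_N)
    if not c_shared:
        labels.add(ALT_C)
    if n_shared and c_shared and w.cds != wo.cds:
        labels.add(ALT_CODING)
    if _intron_retained(favored, other, region):
        labels.add(INTRON_RETENTION)
    return PairEvidence(
        isoform_with=w.transcript_id,
        isoform_without=wo.transcript_id,
        ptc_distance_nt=fav_ptc.distance_nt,
        protein_ratio=ratio,
        labels=frozenset(labels),
    )


def classify_event(
    event,
    models: Sequence[TranscriptModel],
    region: Interval,
    params: ConsequenceParams | None = None,
) -> ConsequenceCall:
    """Predict the protein-level consequences of one event.

    ``event`` needs ``probeset_id``, ``gene_id`` and ``direction``
    attributes (a :class:`~exonsplice.si.SplicingEvent` or any duck-typed
    record).  Pure function: identical inputs give identical calls.  Events
    whose partition is degenerate (all or no isoforms contain the region)
    return an empty consequence set.
    """
    params = params or ConsequenceParams()
    gene_models = [m for m in models if m.gene_id == event.gene_id and m.cds]
    with_, without = partition_isoforms(gene_models, region, params.min_overlap)
    evidence = tuple(
        _pair_labels(w, wo, event.direction, region, params)
        for w in with_ for wo in without
    )
    consequences = frozenset().union(*(ev.labels for ev in evidence)) \
        if evidence else frozenset()
    return ConsequenceCall(
        probeset_id=event.probeset_id,
        gene_id=event.gene_id,
        direction=event.direction,
        consequences=consequences,
        evidence=evidence,
    )


def annotate_events(
    events: pd.DataFrame,
    models: Sequence[TranscriptModel],
    probeset_map: pd.DataFrame,
    params: ConsequenceParams | None = None,
) -> list[ConsequenceCall]:
    """Classify every event row against the annotation.

    ``events`` is the detector output (columns ``probeset_id``, ``gene_id``,
    ``direction``); regions come from ``probeset_map``.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    calls = []
    for row in events.itertuples(index=False):
        prow = probeset_map.loc[row.probeset_id]
        region = (int(prow["start"]), int(prow["end"]))
        calls.append(classify_event(row, by_gene.get(row.gene_id, []),
                                    region, params))
    return calls


def calls_to_frame(calls: Iterable[ConsequenceCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "probeset_id": c.probeset_id,
            "gene_id": c.gene_id,
            "direction": c.direction,
            "consequences": "|".join(sorted(c.consequences)),
            "n_consequences": len(c.consequences),
            "n_isoform_pairs": len(c.evidence),
        })
    return pd.DataFrame(rows, columns=["probeset_id", "gene_id", "direction",
                                       "consequences", "n_consequences",
                                       "n_isoform_pairs"])


@dataclass
class ConsequenceSummary:
    counts: dict
    fractions: dict
    overlap: pd.DataFrame
    n_events: int
    n_predictions: int
    frac_multi: float

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "fractions": dict(self.fractions),
            "overlap": {a: {b: int(self.overlap.loc[a, b]) for b in CATEGORIES}
                        for a in CATEGORIES},
            "n_events": self.n_events,
            "n_predictions": self.n_predictions,
            "frac_multi": self.frac_multi,
        }


def summarize_consequences(calls: Sequence[ConsequenceCall]) -> ConsequenceSummary:
    """Per-category counts/fractions and the co-occurrence (overlap) matrix.

    Fractions are of the total number of functional predictions (an event
    with two consequences contributes two predictions); ``frac_multi`` is
    the fraction of events carrying more than one consequence.
    """
    counts = {c: 0 for c in CATEGORIES}
    overlap = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES))
    n_multi = 0
    total = 0
    for call in calls:
        cs = sorted(call.consequences)
        total += len(cs)
        if len(cs) > 1:
            n_multi += 1
        for a in cs:
            counts[a] += 1
            for b in cs:
                if b != a:
                    overlap.loc[a, b] += 1
    fractions = {c: (counts[c] / total if total else 0.0) for c in CATEGORIES}
    return ConsequenceSummary(
        counts=counts, fractions=fractions, overlap=overlap,
        n_events=len(calls), n_predictions=total,
        frac_multi=(n_multi / len(calls) if calls else 0.0),
    )
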