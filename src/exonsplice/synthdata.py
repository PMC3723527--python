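"""Synthetic exon-array cohorts with planted splicing events of known consequence.

The generator emits everything the analysis consumes — a GTF annotation,
probe-set (and optionally probe-level) log2 intensity matrices, DABG
p-values, a sample design table — plus a truth table recording every
planted event and the consequence set the structural classifier must
recover for it.

The stated world it emulates: two or three sample groups (healthy
``control``, patient ``case``, and an optional ``post``-treatment group
paired with the patients by subject), log-normal probe intensities
(additive Gaussian on the log2 scale), per-gene baselines, fixed per-probe
affinities, subject random intercepts shared across a subject's states, and
planted exon inclusion/exclusion events that shift the affected probe-set
by ``effect_log2`` in the case group (the effect reverts in the paired
post-treatment group, emulating treatment reversal).  A configurable
fraction of genes receive a whole-gene expression shift (confounders that
gene-level normalization must cancel) and a configurable fraction of
probe-sets are unexpressed decoys exercising the detection filter.

Event geometry is engineered per consequence class so the planted truth
labels follow from construction arithmetic alone (independent of the
classifier module): cassette exons whose annotated CDS places a stop
> 50 nt upstream of the final junction (NMD), isoform pairs whose coding
lengths differ by more than half (truncation), alternative first/last
exons (altN/altC), retained introns, and in-frame cassettes (alt_coding).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import exprio
from .exprio import ExpressionSet, Interval, TranscriptModel

INCLUSION = "inclusion"
EXCLUSION = "exclusion"

TRUTH_COLUMNS = ["gene_id", "probeset_id", "direction", "consequences", "effect_log2"]

_OTHER_CYCLE = ("altN", "altC", "intron_retention", "alt_coding")

_GENE_GAP = 5000


class ConfigurationError(ValueError):
    """Raised when a simulation configuration demands impossible structures."""


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration.  Defaults state the emulated world.

    Sample sizes default to 8 vs 8 (the scale of the leukocyte cohorts:
    7 patients / 6 controls, and 17 / 11 in the whole-blood set); effect
    and noise defaults (2.0 and 0.25 log2 units) describe a strong planted
    inclusion shift over typical RMA-summarized array noise.
    """

    n_genes: int = 100
    isoforms_per_gene: tuple[int, int] = (2, 2)
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (60, 180)
    n_control: int = 8
    n_case: int = 8
    paired_followup: bool = False
    probe_sets_per_exon: int = 1
    probes_per_probe_set: int = 4
    probe_level: bool = False
    log2_baseline_mean: float = 8.0
    log2_baseline_sd: float = 1.5
    noise_sd: float = 0.25
    event_fraction: float = 0.3
    effect_log2: float = 2.0
    nmd_event_fraction: float = 0.25
    truncation_event_fraction: float = 0.15
    gene_level_confounder_fraction: float = 0.1
    confounder_log2: float = 1.0
    decoy_fraction: float = 0.1
    affinity_sd: float = 0.4
    probe_affinity_sd: float = 0.4
    subject_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("event_fraction", "nmd_event_fraction",
                     "truncation_event_fraction",
                     "gene_level_confounder_fraction", "decoy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_genes", "n_control", "n_case", "probe_sets_per_exon",
                     "probes_per_probe_set"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for name in ("isoforms_per_gene", "exons_per_gene", "exon_length"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ConfigurationError(f"{name} must be a (lo, hi) range with "
                                         f"1 <= lo <= hi, got ({lo}, {hi})")
        if self.exon_length[0] < 30:
            raise ConfigurationError("exon_length minimum must be >= 30 nt")
        if self.event_fraction > 0:
            if self.isoforms_per_gene[1] < 2:
                raise ConfigurationError(
                    "planting events requires genes with >= 2 isoforms")
            if self.exons_per_gene[1] < 3:
                raise ConfigurationError(
                    "planting events (e.g. intron retention, cassette exons) "
                    "requires genes with >= 3 exons")
        if self.nmd_event_fraction + self.truncation_event_fraction > 1.0:
            raise ConfigurationError(
                "nmd_event_fraction + truncation_event_fraction must be <= 1")


@dataclass
class GeneDesign:
    """One gene's local-coordinate layout before genomic placement."""

    exons_by_isoform: list[list[Interval]]
    cds_by_isoform: list[list[Interval]]
    regions: list[Interval]               # probe-set target regions
    event_region_idx: int | None = None
    direction: str | None = None
    consequences: frozenset = frozenset()


@dataclass
class SimResult:
    config: SimConfig
    models: list[TranscriptModel]
    probeset_map: pd.DataFrame
    truth: pd.DataFrame
    expression: ExpressionSet
    probes: pd.DataFrame | None = None
    probe_to_ps: pd.Series | None = None
    confounders: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# engineered gene layouts (local plus-strand coordinates, gene starts at 0)
# ---------------------------------------------------------------------------

def _chain(lengths: Sequence[int], intron: int = 300) -> list[Interval]:
    """Lay exons of the given lengths along a local axis with fixed introns."""
    out, pos = [], 0
    for L in lengths:
        out.append((pos, pos + L))
        pos += L + intron
    return out


def _cds_through(exons: Sequence[Interval], start_off: int, stop_exon: int,
                 stop_off: int) -> list[Interval]:
    """CDS from ``start_off`` into exon 0 through ``stop_off`` into exon
    ``stop_exon`` (local plus-strand coordinates)."""
    cds = []
    for i, (a, b) in enumerate(exons):
        if i > stop_exon:
            break
        s = a + start_off if i == 0 else a
        e = a + stop_off if i == stop_exon else b
        if e > s:
            cds.append((s, e))
    return cds


def _fit_frame(length: int) -> int:
    """Smallest non-negative pad making ``length`` a codon multiple."""
    return (3 - length % 3) % 3


def _draw_len(rng: np.random.Generator, cfg: SimConfig, lo: int = 0) -> int:
    return int(max(lo, rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1)))


def _design_plain(rng: np.random.Generator, cfg: SimConfig) -> GeneDesign:
    """A no-event gene: full isoform plus (optionally) one skipping an
    in-frame neutral exon, giving realistic non-constitutive nulls."""
    n = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    n = max(n, 1)
    lens = [_draw_len(rng, cfg) for _ in range(n)]
    n_iso = int(rng.integers(cfg.isoforms_per_gene[0], cfg.isoforms_per_gene[1] + 1))
    skip = None
    if n_iso >= 2 and n >= 3:
        skip = int(rng.integers(1, n - 1))
        lens[skip] += _fit_frame(lens[skip])          # keep the skip in-frame
    exons = _chain(lens)
    stop_off = min(30, lens[-1] - 3)
    coding = (lens[0] - 9) + sum(lens[1:-1]) + stop_off if n > 1 else lens[0] - 9 - 3
    if n > 1:
        stop_off += _fit_frame(coding)
        cds_a = _cds_through(exons, 9, n - 1, stop_off)
    else:
        end = lens[0] - 3
        end -= (end - 9) % 3
        cds_a = [(9, end)]
    isoforms = [exons]
    cds = [cds_a]
    if skip is not None:
        exons_b = [e for i, e in enumerate(exons) if i != skip]
        # the skipped exon is internal and fully coding; drop its CDS piece
        cds_b = [c for c in cds_a if not (c[0] >= exons[skip][0] and c[1] <= exons[skip][1])]
        isoforms.append(exons_b)
        cds.append(cds_b)
    return GeneDesign(isoforms, cds, regions=list(exons))


def _design_nmd(rng: np.random.Generator, cfg: SimConfig) -> GeneDesign:
    """NMD gene: inclusion-triggered NMD (used when a comparison needs a
    generic NMD gene); planted cohorts alternate this with the exclusion
    variant so both mechanisms appear, mirroring cohorts in which both
    inclusion and exclusion events feed decay.  Mixed directions also keep
    the NMD signature informative under correlation distance (a
    single-direction signature is a per-sample offset, to which correlation
    is blind)."""
    return _design_nmd_inclusion(rng, cfg)


def _design_nmd_inclusion(rng: np.random.Generator, cfg: SimConfig) -> GeneDesign:
    """Cassette exon whose inclusion isoform stops > 50 nt upstream of its
    final junction; exclusion isoform stops normally in the last exon.
    Planted labels: {NMD, altC} (stops differ, starts shared; coding
    lengths are close, so truncation cannot fire)."""
    l0, l1 = _draw_len(rng, cfg), _draw_len(rng, cfg)
    l2 = max(_draw_len(rng, cfg), 84)                 # cassette, room for PTC
    l3 = _draw_len(rng, cfg)
    exons = _chain([l0, l1, l2, l3])
    stop_c = 21 + _fit_frame((l0 - 9) + l1 + 21)
    cds_with = _cds_through(exons, 9, 2, stop_c)
    stop_l = 30 + _fit_frame((l0 - 9) + l1 + 30)
    exons_wo = [exons[0], exons[1], exons[3]]
    cds_wo = _cds_through(exons_wo, 9, 2, stop_l)
    return GeneDesign(
        [exons, exons_wo], [cds_with, cds_wo], regions=list(exons),
        event_region_idx=2, direction=INCLUSION,
        consequences=frozenset({"NMD", "altC"}))


def _design_nmd_exclusion(rng: np.random.Generator, cfg: SimConfig) -> GeneDesign:
    """Skipping the cassette shifts the frame so the exclusion isoform's
    stop lands 60 nt upstream of its final junction (PTC), while the full
    isoform stops normally.  Geometry is fixed so the coding-length ratio
    stays above one half: planted labels {NMD, altC}."""
    l0, l1, l2, l3 = 180, 150, 60, 120
    exons = _chain([l0, l1, l2, l3])
    s3 = 12 + _fit_frame((l0 - 9) + l1 + l2 + 12)
    cds_full = _cds_through(exons, 9, 3, s3)
    exons_wo = [exons[0], exons[1], exons[3]]
    s1 = 90 + _fit_frame((l0 - 9) + 90)               # stop 60 nt before junction
    cds_wo = _cds_through(exons_wo, 9, 1, s1)
    return GeneDesign(
        [exons, exons_wo], [cds_full, cds_wo], regions=list(exons),
        event_region_idx=2, direction=EXCLUSION,
        consequences=frozenset({"NMD", "altC"}))


def _design_truncation(rng: np.random.Generator, cfg: SimConfig) -> GeneDesign:
    """Skipping the cassette truncates the protein to ~12% of full length
    with the alternative stop early in the final exon (no PTC).  Exclusion
    event; planted labels {truncation, altC}."""
    l0, l1, l2 = 42, 150, 210
    exons = _chain([l0, l1, l2])
    k2 = (l2 - 24) - ((l0 - 9) + l1 + (l2 - 24)) % 3
    cds_full = _cds_through(exons, 9, 2, k2)
    s2 = 12 + _fit_frame((l0 - 9) + 12)
    exons_wo = [exons[0], exons[2]]
    cds_wo = _cds_through(exons_wo, 9, 1, s2)
    return GeneDesign(
        [exons, exons_wo], [cds_full, cds_wo], regions=list(exons),
        event_region_idx=1, direction=EXCLUSION,
        consequences=frozenset({"truncation", "altC"}))


def _design_altn(rng: np.random.Generator, cfg: SimConfig) -> GeneDesign:
    """Alternative first exons with different CDS starts, shared stop."""
    l0a, l0b = 90, 90
    l1, l2 = _draw_len(rng, cfg), _draw_len(rng, cfg)
    e0a = (0, l0a)
    e0b = (l0a + 300, l0a + 300 + l0b)
    shared = _chain([l1, l2])
    off = e0b[1] + 300
    shared = [(a + off, b + off) for a, b in shared]
    exons_a = [e0a] + shared
    exons_b = [e0b] + shared
    s = 30 + _fit_frame((l0a - 9) + l1 + 30)
    cds_a = _cds_through(exons_a, 9, 2, s)
    cds_b = _cds_through(exons_b, 30, 2, s)           # 81 vs 60 nt first piece
    regions = [e0a, e0b] + shared
    return GeneDesign(
        [exons_a, exons_b], [cds_a, cds_b], regions=regions,
        event_region_idx=0, direction=INCLUSION,
        consequences=frozenset({"altN"}))


def _design_altc(rng: np.random.Generator, cfg: SimConfig) -> GeneDesign:
    """Alternative last exons; shared start, different stops."""
    l0, l1 = _draw_len(rng, cfg), _draw_len(rng, cfg)
    l2a, l2b = 120, 120
    head = _chain([l0, l1])
    off = head[-1][1] + 300
    e2a = (off, off + l2a)
    e2b = (e2a[1] + 300, e2a[1] + 300 + l2b)
    exons_a = head + [e2a]
    exons_b = head + [e2b]
    sa = 45 + _fit_frame((l0 - 9) + l1 + 45)
    sb = 60 + _fit_frame((l0 - 9) + l1 + 60)
    cds_a = _cds_through(exons_a, 9, 2, sa)
    cds_b = _cds_through(exons_b, 9, 2, sb)
    regions = head + [e2a, e2b]
    return GeneDesign(
        [exons_a, exons_b], [cds_a, cds_b], regions=regions,
        event_region_idx=2, direction=INCLUSION,
        consequences=frozenset({"altC"}))


def _design_intron_retention(rng: np.random.Generator, cfg: SimConfig) -> GeneDesign:
    """One isoform retains the (150 nt, in-frame) intron as coding sequence.
    Shared termini + changed internal CDS make alt_coding co-occur."""
    e0, e1 = (0, 150), (300, 450)
    retained = [(0, 450)]
    s = 45                                            # 141 + 45 = 186 = 62 codons
    cds_spliced = [(9, 150), (300, 300 + s)]
    cds_retained = [(9, 300 + s)]
    regions = [e0, e1, (150, 300)]                    # intron gets a probe-set
    return GeneDesign(
        [retained, [e0, e1]], [cds_retained, cds_spliced], regions=regions,
        event_region_idx=2, direction=INCLUSION,
        consequences=frozenset({"intron_retention", "alt_coding"}))


def _design_alt_coding(rng: np.random.Generator, cfg: SimConfig) -> GeneDesign:
    """In-frame cassette inside the CDS; termini shared.  Exclusion event."""
    l0 = max(_draw_len(rng, cfg), 60)
    l1 = 90                                           # in-frame cassette
    l2 = max(_draw_len(rng, cfg), 120)
    exons = _chain([l0, l1, l2])
    s = 60 + _fit_frame((l0 - 9) + l1 + 60)
    cds_a = _cds_through(exons, 9, 2, s)
    exons_b = [exons[0], exons[2]]
    cds_b = [c for c in cds_a if not (c[0] >= exons[1][0] and c[1] <= exons[1][1])]
    return GeneDesign(
        [exons, exons_b], [cds_a, cds_b], regions=list(exons),
        event_region_idx=1, direction=EXCLUSION,
        consequences=frozenset({"alt_coding"}))


_BUILDERS = {
    "NMD": _design_nmd,
    "NMD_incl": _design_nmd_inclusion,
    "NMD_excl": _design_nmd_exclusion,
    "truncation": _design_truncation,
    "altN": _design_altn,
    "altC": _design_altc,
    "intron_retention": _design_intron_retention,
    "alt_coding": _design_alt_coding,
}


# ---------------------------------------------------------------------------
# annotation assembly
# ---------------------------------------------------------------------------

def _mirror(iv: Interval, span: int) -> Interval:
    return (span - iv[1], span - iv[0])


def _event_types(rng: np.random.Generator, cfg: SimConfig) -> list[str | None]:
    """Per-gene planted event type (None for no event), deterministic in seed."""
    n_ev = int(round(cfg.event_fraction * cfg.n_genes))
    n_nmd = int(round(cfg.nmd_event_fraction * n_ev))
    n_tr = int(round(cfg.truncation_event_fraction * n_ev))
    n_tr = min(n_tr, n_ev - n_nmd)
    # alternate the two NMD mechanisms so directions stay balanced
    types = [("NMD_incl" if i % 2 == 0 else "NMD_excl") for i in range(n_nmd)]
    types += ["truncation"] * n_tr
    types += [_OTHER_CYCLE[i % len(_OTHER_CYCLE)] for i in range(n_ev - len(types))]
    rng.shuffle(types)
    slots: list[str | None] = [None] * cfg.n_genes
    for gi, t in zip(sorted(rng.permutation(cfg.n_genes)[:n_ev]), types):
        slots[int(gi)] = t
    return slots


def simulate_annotation(
    config: SimConfig,
) -> tuple[list[TranscriptModel], pd.DataFrame, pd.DataFrame]:
    """Build transcript models, the probe-set map and the truth table.

    Each gene keeps at least one constitutive exon; strands are mixed; the
    truth table's ``consequences`` column is fixed by construction
    arithmetic (see the per-type builders), never by running the
    classifier.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    types = _event_types(rng, config)

    models: list[TranscriptModel] = []
    map_rows: list[dict] = []
    truth_rows: list[dict] = []
    offset = 1000
    chrom = "chrS"
    width = max(4, len(str(config.n_genes)))

    for gi, ev_type in enumerate(types):
        gid = f"G{gi + 1:0{width}d}"
        strand = "+" if rng.random() < 0.5 else "-"
        design = (_BUILDERS[ev_type] if ev_type else _design_plain)(rng, config)

        span = max(b for iso in design.exons_by_isoform for _, b in iso)
        place = (lambda iv: (_mirror(iv, span)[0] + offset,
                             _mirror(iv, span)[1] + offset)) if strand == "-" \
            else (lambda iv: (iv[0] + offset, iv[1] + offset))

        iso_names = "AB"
        for k, (exons, cds) in enumerate(
                zip(design.exons_by_isoform, design.cds_by_isoform)):
            models.append(TranscriptModel(
                gene_id=gid, transcript_id=f"{gid}.{iso_names[k]}",
                chrom=chrom, strand=strand,
                exons=tuple(place(iv) for iv in exons),
                cds=tuple(place(iv) for iv in cds)))
        gene_models = models[-len(design.exons_by_isoform):]

        # probe-sets: split every target region into probe_sets_per_exon chunks
        psi = 0
        event_ps: list[str] = []
        for ri, region in enumerate(design.regions):
            g_region = place(region)
            bounds = np.linspace(g_region[0], g_region[1],
                                 config.probe_sets_per_exon + 1).astype(int)
            for j in range(config.probe_sets_per_exon):
                psi += 1
                ps_id = f"{gid}_ps{psi:02d}"
                s, e = int(bounds[j]), int(bounds[j + 1])
                constitutive = all(m.contains_region((s, e), min_overlap=1.0)
                                   for m in gene_models)
                map_rows.append({"probeset_id": ps_id, "gene_id": gid,
                                 "chrom": chrom, "start": s, "end": e,
                                 "constitutive": constitutive, "tier": "core",
                                 "decoy": False})
                if ri == design.event_region_idx:
                    event_ps.append(ps_id)

        if ev_type is not None:
            signed = (config.effect_log2 if design.direction == INCLUSION
                      else -config.effect_log2)
            for ps_id in event_ps:
                truth_rows.append({
                    "gene_id": gid, "probeset_id": ps_id,
                    "direction": design.direction,
                    "consequences": "|".join(sorted(design.consequences)),
                    "effect_log2": signed})
        offset += span + _GENE_GAP

    pmap = pd.DataFrame(map_rows).set_index("probeset_id")

    # decoy "absent" probe-sets inside first introns of non-event genes
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    n_decoy = int(round(config.decoy_fraction * len(pmap)))
    eligible = [m for m in models
                if m.transcript_id.endswith(".A") and len(m.exons) >= 2
                and m.gene_id not in set(truth["gene_id"])]
    decoy_rows = []
    if not eligible:
        n_decoy = 0
    for i in range(n_decoy):
        m = eligible[int(rng.integers(len(eligible)))]
        ia, ib = m.introns[0]
        if ib - ia < 80:
            continue
        s = ia + 20
        decoy_rows.append({"probeset_id": f"{m.gene_id}_dk{i + 1:02d}",
                           "gene_id": m.gene_id, "chrom": m.chrom,
                           "start": s, "end": s + 40,
                           "constitutive": False, "tier": "core", "decoy": True})
    if decoy_rows:
        pmap = pd.concat([pmap, pd.DataFrame(decoy_rows).set_index("probeset_id")])
    return models, pmap, truth


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def _design_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for i in range(config.n_control):
        rows.append({"sample": f"HC{i + 1:02d}", "group": "control",
                     "subject": pd.NA})
    for i in range(config.n_case):
        sid = f"S{i + 1:02d}" if config.paired_followup else pd.NA
        rows.append({"sample": f"PD{i + 1:02d}", "group": "case", "subject": sid})
    if config.paired_followup:
        for i in range(config.n_case):
            rows.append({"sample": f"ON{i + 1:02d}", "group": "post",
                         "subject": f"S{i + 1:02d}"})
    return pd.DataFrame(rows).set_index("sample")


def simulate_expression(
    models: Sequence[TranscriptModel],
    probeset_map: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimConfig,
) -> tuple[ExpressionSet, pd.DataFrame | None, pd.Series | None, pd.DataFrame]:
    """Generate intensities, DABG p-values, design (and probe-level data).

    log2 intensity = gene baseline + probe-set affinity + subject intercept
    + planted group effect + whole-gene confounder shift + N(0, noise_sd).
    Returns ``(expression_set, probes, probe_to_ps, confounders)``.
    """
    config.validate()
    gene_ids = sorted({m.gene_id for m in models})
    if not set(probeset_map["gene_id"]).issubset(gene_ids):
        raise ConfigurationError("probe-set map references genes absent from models")
    if len(truth) and not set(truth["probeset_id"]).issubset(probeset_map.index):
        raise ConfigurationError("truth table references unknown probe-sets")

    rng = np.random.default_rng([config.seed, 1])
    design = _design_table(config)
    samples = list(design.index)
    n_s = len(samples)

    baseline = pd.Series(
        rng.normal(config.log2_baseline_mean, config.log2_baseline_sd,
                   len(gene_ids)), index=gene_ids)
    # whole-gene confounder shifts on event-free genes (case group only)
    event_genes = set(truth["gene_id"]) if len(truth) else set()
    free = [g for g in gene_ids if g not in event_genes]
    n_conf = min(int(round(config.gene_level_confounder_fraction * len(gene_ids))),
                 len(free))
    conf_idx = sorted(rng.permutation(len(free))[:n_conf])
    conf_rows = [{"gene_id": free[i],
                  "shift_log2": config.confounder_log2 * (1 if k % 2 == 0 else -1)}
                 for k, i in enumerate(conf_idx)]
    confounders = pd.DataFrame(conf_rows, columns=["gene_id", "shift_log2"])
    conf_shift = dict(zip(confounders["gene_id"], confounders["shift_log2"]))

    subject_eff = {s: rng.normal(0.0, config.subject_sd)
                   for s in design["subject"].dropna().unique()}
    sample_eff = np.array([
        subject_eff[design.loc[s, "subject"]]
        if pd.notna(design.loc[s, "subject"])
        else rng.normal(0.0, config.subject_sd)
        for s in samples])

    effect = dict(zip(truth["probeset_id"], truth["effect_log2"])) if len(truth) else {}
    is_case = (design["group"] == "case").to_numpy()

    ps_ids = list(probeset_map.index)
    affinity = pd.Series(rng.normal(0.0, config.affinity_sd, len(ps_ids)),
                         index=ps_ids)
    decoy = probeset_map["decoy"].astype(bool) if "decoy" in probeset_map.columns \
        else pd.Series(False, index=probeset_map.index)

    signal = np.empty((len(ps_ids), n_s))
    dabg = np.empty_like(signal)
    for r, ps in enumerate(ps_ids):
        g = probeset_map.loc[ps, "gene_id"]
        if decoy[ps]:
            signal[r] = 4.0
            dabg[r] = rng.uniform(0.5, 1.0, n_s)
            continue
        base = baseline[g] + affinity[ps] + sample_eff
        if g in conf_shift:
            base = base + conf_shift[g] * is_case
        if ps in effect:
            base = base + effect[ps] * is_case
        signal[r] = base
        dabg[r] = rng.uniform(0.0, 1e-3, n_s)

    noise = rng.normal(0.0, config.noise_sd, signal.shape) if config.noise_sd > 0 \
        else 0.0
    inten = pd.DataFrame(signal + noise, index=ps_ids, columns=samples)
    dabg_df = pd.DataFrame(dabg, index=ps_ids, columns=samples)
    es = ExpressionSet(intensities=inten, probeset_map=probeset_map,
                       dabg=dabg_df, design=design)

    probes = probe_to_ps = None
    if config.probe_level:
        probe_ids, ps_of_probe, rows = [], [], []
        for r, ps in enumerate(ps_ids):
            offs = rng.normal(0.0, config.probe_affinity_sd,
                              config.probes_per_probe_set)
            pnoise = (rng.normal(0.0, config.noise_sd,
                                 (config.probes_per_probe_set, n_s))
                      if config.noise_sd > 0 else 0.0)
            block = signal[r][None, :] + offs[:, None] + pnoise
            for j in range(config.probes_per_probe_set):
                probe_ids.append(f"{ps}_p{j + 1}")
                ps_of_probe.append(ps)
            rows.append(block)
        probes = pd.DataFrame(np.vstack(rows), index=probe_ids, columns=samples)
        probe_to_ps = pd.Series(ps_of_probe, index=probe_ids, name="probeset_id")
    return es, probes, probe_to_ps, confounders


def simulate(config: SimConfig) -> SimResult:
    """End-to-end generation: annotation, truth and expression."""
    models, pmap, truth = simulate_annotation(config)
    es, probes, probe_to_ps, confounders = simulate_expression(
        models, pmap, truth, config)
    return SimResult(config=config, models=models, probeset_map=pmap,
                     truth=truth, expression=es, probes=probes,
                     probe_to_ps=probe_to_ps, confounders=confounders)


def write_simulation(result: SimResult, out_dir: str | Path) -> dict[str, Path]:
    """Write every artifact as deterministic plain text; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = exprio.write_expression_set(result.expression, out)
    paths["gtf"] = out / "annotation.gtf"
    exprio.write_annotation(result.models, paths["gtf"])
    paths["truth"] = out / "truth.tsv"
    result.truth.to_csv(paths["truth"], sep="\t", index=False,
                        float_format=exprio.FLOAT_FORMAT)
    if result.confounders is not None:
        paths["confounders"] = out / "confounders.tsv"
        result.confounders.to_csv(paths["confounders"], sep="\t", index=False,
                                  float_format=exprio.FLOAT_FORMAT)
    if result.probes is not None:
        paths["probes"] = out / "probes.tsv"
        pl = result.probes.copy()
        pl.insert(0, "probeset_id", result.probe_to_ps)
        pl.to_csv(paths["probes"], sep="\t", index_label="probe_id",
                  float_format=exprio.FLOAT_FORMAT)
    paths["config"] = out / "sim_config.json"
    paths["config"].write_text(json.dumps(asdict(result.config), indent=2,
                                          sort_keys=True) + "\n")
    return paths


def read_probes(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a probe-level matrix written by :func:`write_simulation`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    probe_to_ps = df["probeset_id"].astype(str)
    return df.drop(columns=["probeset_id"]).astype(float), probe_to_ps
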