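"""Readers, writers and in-memory containers for exon-array splicing analysis.

Two containers anchor the pipeline: :class:`TranscriptModel`, one isoform's
exon/CDS structure (the substrate of protein-level consequence prediction),
and :class:`ExpressionSet`, the probe-set x sample intensity matrix together
with detection p-values, the sample design and the probe-set -> gene map.

Genomic coordinates are 0-based half-open internally.  GTF input/output
converts to and from the 1-based inclusive convention of that format.
Intensities are stored on the log2 scale throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

Interval = tuple[int, int]

MAP_COLUMNS = ["gene_id", "chrom", "start", "end", "constitutive", "tier"]


class AnnotationError(ValueError):
    """Raised for structurally invalid transcript annotations."""


class ExpressionIOError(ValueError):
    """Raised for malformed or mutually inconsistent expression inputs."""


def _as_intervals(ivs: Iterable[Sequence[int]]) -> tuple[Interval, ...]:
    out = tuple(sorted((int(a), int(b)) for a, b in ivs))
    for a, b in out:
        if b <= a:
            raise AnnotationError(f"empty or inverted interval ({a}, {b})")
    for (_, b0), (a1, _) in zip(out, out[1:]):
        if a1 < b0:
            raise AnnotationError(f"overlapping intervals at {a1} < {b0}")
    return out


@dataclass(frozen=True)
class TranscriptModel:
    """One isoform: ordered exon intervals plus an optional CDS.

    ``exons`` and ``cds`` are stored in ascending genomic order; strand-aware
    (5' -> 3') views are exposed through ``exons_stranded``/``cds_stranded``.
    The CDS is taken to include the stop codon.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}")
        object.__setattr__(self, "exons", _as_intervals(self.exons))
        object.__setattr__(self, "cds", _as_intervals(self.cds) if self.cds else ())
        for a, b in self.cds:
            if not any(ea <= a and b <= eb for ea, eb in self.exons):
                raise AnnotationError(
                    f"{self.transcript_id}: CDS interval ({a}, {b}) outside exons")

    # ---- strand-aware views -------------------------------------------------

    @property
    def exons_stranded(self) -> tuple[Interval, ...]:
        """Exons in transcription (5'->3') order."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    @property
    def cds_stranded(self) -> tuple[Interval, ...]:
        return self.cds if self.strand == "+" else tuple(reversed(self.cds))

    # ---- derived lengths and spliced coordinates ----------------------------

    @property
    def spliced_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def coding_length(self) -> int:
        return sum(b - a for a, b in self.cds)

    @property
    def frame_valid(self) -> bool:
        """True when the annotated CDS length is a whole number of codons."""
        return bool(self.cds) and self.coding_length % 3 == 0

    @property
    def protein_length_aa(self) -> int:
        """Protein product length in residues, excluding the stop codon."""
        if not self.cds:
            return 0
        return max(self.coding_length // 3 - 1, 0)

    def spliced_offset(self, gpos: int) -> int:
        """0-based position of genomic base ``gpos`` in spliced coordinates."""
        off = 0
        for a, b in self.exons_stranded:
            if a <= gpos < b:
                return off + (gpos - a if self.strand == "+" else b - 1 - gpos)
            off += b - a
        raise ValueError(f"{self.transcript_id}: position {gpos} is not exonic")

    @property
    def final_junction_spliced(self) -> int | None:
        """Spliced coordinate of the last exon-exon junction (None if 1 exon)."""
        if len(self.exons) < 2:
            return None
        last = self.exons_stranded[-1]
        return self.spliced_length - (last[1] - last[0])

    @property
    def stop_spliced_end(self) -> int | None:
        """Spliced coordinate just past the 3'-most CDS base (stop codon end)."""
        if not self.cds:
            return None
        if self.strand == "+":
            gpos = self.cds[-1][1] - 1
        else:
            gpos = self.cds[0][0]
        return self.spliced_offset(gpos) + 1

    # ---- termini anchors (genomic positions of the CDS ends) ---------------

    @property
    def cds_start_genomic(self) -> int | None:
        """Genomic coordinate anchoring the N-terminus (strand-aware 5' CDS end)."""
        if not self.cds:
            return None
        return self.cds[0][0] if self.strand == "+" else self.cds[-1][1]

    @property
    def cds_end_genomic(self) -> int | None:
        """Genomic coordinate anchoring the C-terminus (strand-aware 3' CDS end)."""
        if not self.cds:
            return None
        return self.cds[-1][1] if self.strand == "+" else self.cds[0][0]

    # ---- interval helpers ---------------------------------------------------

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple((b0, a1) for (_, b0), (a1, _) in zip(self.exons, self.exons[1:]))

    def exonic_overlap(self, region: Interval) -> int:
        s, e = region
        return sum(max(0, min(e, b) - max(s, a)) for a, b in self.exons)

    def contains_region(self, region: Interval, min_overlap: float = 0.5) -> bool:
        """True when >= ``min_overlap`` of the region lies within this isoform's exons."""
        s, e = region
        return self.exonic_overlap(region) >= min_overlap * (e - s)


# ---------------------------------------------------------------------------
# ExpressionSet
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSet:
    """Probe-set x sample log2 intensities with DABG p-values, design and map.

    Invariants enforced at construction: the DABG matrix shares the intensity
    matrix's row/column labels (it is reindexed to the same ordering); every
    probe-set in the matrix appears in ``probeset_map``; subject identifiers,
    when present, pair two or three samples from distinct groups.
    """

    intensities: pd.DataFrame
    probeset_map: pd.DataFrame
    dabg: pd.DataFrame | None = None
    design: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        orphans = self.intensities.index.difference(self.probeset_map.index)
        if len(orphans):
            raise ExpressionIOError(
                "probe-sets absent from the probe-set map: "
                + ", ".join(map(str, orphans[:10])))
        if self.dabg is not None:
            missing_r = self.intensities.index.difference(self.dabg.index)
            missing_c = self.intensities.columns.difference(self.dabg.columns)
            if len(missing_r) or len(missing_c):
                raise ExpressionIOError(
                    f"DABG matrix is missing rows {list(missing_r[:5])} "
                    f"/ columns {list(missing_c[:5])}")
            self.dabg = self.dabg.loc[self.intensities.index, self.intensities.columns]
        if self.design is not None:
            extra = self.intensities.columns.difference(self.design.index)
            if len(extra):
                raise ExpressionIOError(
                    f"samples absent from the design table: {list(extra[:10])}")
            self.design = self.design.loc[self.intensities.columns]
            self._check_pairing()

    def _check_pairing(self) -> None:
        subj = self.design["subject"].dropna()
        for sid, rows in self.design.loc[subj.index].groupby("subject"):
            if not 2 <= len(rows) <= 3:
                raise ExpressionIOError(
                    f"subject {sid!r} labels {len(rows)} samples; expected 2 or 3")
            if rows["group"].nunique() != len(rows):
                raise ExpressionIOError(
                    f"subject {sid!r} has repeated group labels: "
                    f"{sorted(rows['group'])}")

    # ---- convenience --------------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    def samples_in(self, group: str) -> list[str]:
        if self.design is None:
            raise ExpressionIOError("no design table loaded")
        hits = self.design.index[self.design["group"] == group]
        if not len(hits):
            raise ExpressionIOError(f"condition {group!r} absent from the design")
        return list(hits)

    def subset(self, probesets: Iterable[str]) -> "ExpressionSet":
        idx = self.intensities.index.intersection(pd.Index(probesets))
        return ExpressionSet(
            intensities=self.intensities.loc[idx],
            probeset_map=self.probeset_map,
            dabg=None if self.dabg is None else self.dabg.loc[idx],
            design=self.design,
        )

    def gene_of(self) -> pd.Series:
        """Gene id per probe-set row, aligned to the intensity matrix."""
        return self.probeset_map.loc[self.intensities.index, "gene_id"]


# ---------------------------------------------------------------------------
# Tabular readers/writers
# ---------------------------------------------------------------------------

def _read_numeric_matrix(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ExpressionIOError(
                f"{what} {path}: non-numeric cell at row {row!r}, column {col!r}")
        df[col] = vals
    return df.astype(float)


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"sample", "group"}
    if not need.issubset(df.columns):
        raise ExpressionIOError(f"design {path}: needs columns {sorted(need)}")
    if "subject" not in df.columns:
        df["subject"] = pd.NA
    df["subject"] = df["subject"].replace("", pd.NA)
    return df.set_index("sample")[["group", "subject"]]


def read_probeset_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("probeset_id")
    for col in ("start", "end"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    if "constitutive" in df.columns:
        df["constitutive"] = df["constitutive"].map(
            {"True": True, "False": False, "1": True, "0": False})
    if "tier" not in df.columns:
        df["tier"] = "core"
    return df


def load_expression(
    matrix_path: str | Path,
    map_path: str | Path,
    dabg_path: str | Path | None = None,
    design_path: str | Path | None = None,
    scale: str = "auto",
    models: Sequence[TranscriptModel] | None = None,
) -> ExpressionSet:
    """Assemble an :class:`ExpressionSet` from tab-delimited files.

    ``scale`` is one of ``auto`` (log2-transform when the matrix looks
    linear, i.e. its maximum exceeds 30), ``log2`` or ``linear``.  When the
    map file lacks a ``constitutive`` column it is inferred from ``models``.
    """
    inten = _read_numeric_matrix(matrix_path, "expression matrix")
    if scale not in ("auto", "log2", "linear"):
        raise ValueError(f"unknown scale {scale!r}")
    linear = scale == "linear" or (scale == "auto" and np.nanmax(inten.to_numpy()) > 30)
    if linear:
        if (inten.to_numpy() <= 0).any():
            raise ExpressionIOError(
                "linear-scale matrix contains non-positive values; cannot log2")
        inten = np.log2(inten)

    pmap = read_probeset_map(map_path)
    if "constitutive" not in pmap.columns or pmap["constitutive"].isna().any():
        if models is None:
            raise ExpressionIOError(
                "probe-set map lacks a 'constitutive' column and no transcript "
                "models were supplied to infer it")
        pmap["constitutive"] = infer_constitutive(pmap, models)

    dabg = None
    if dabg_path is not None:
        dabg = _read_numeric_matrix(dabg_path, "DABG matrix")
        mismatch = set(dabg.columns) ^ set(inten.columns)
        if mismatch:
            raise ExpressionIOError(
                f"sample sets differ between matrix and DABG: {sorted(mismatch)}")
    design = read_design(design_path) if design_path is not None else None
    if design is not None:
        mismatch = set(design.index) ^ set(inten.columns)
        if mismatch:
            raise ExpressionIOError(
                f"sample sets differ between matrix and design: {sorted(mismatch)}")
    return ExpressionSet(intensities=inten, probeset_map=pmap, dabg=dabg, design=design)


def infer_constitutive(
    probeset_map: pd.DataFrame, models: Sequence[TranscriptModel]
) -> pd.Series:
    """A probe-set is constitutive iff its region lies in every isoform of its gene."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    flags = {}
    for ps, row in probeset_map.iterrows():
        isoforms = by_gene.get(row["gene_id"], [])
        region = (int(row["start"]), int(row["end"]))
        flags[ps] = bool(isoforms) and all(
            m.contains_region(region, min_overlap=1.0) for m in isoforms)
    return pd.Series(flags, name="constitutive")


FLOAT_FORMAT = "%.6f"


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "probeset_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FORMAT)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index_label="sample")


def write_probeset_map(pmap: pd.DataFrame, path: str | Path) -> None:
    pmap.to_csv(path, sep="\t", index_label="probeset_id")


def write_expression_set(es: ExpressionSet, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"matrix": out / "expression.tsv", "map": out / "probeset_map.tsv"}
    write_matrix(es.intensities, paths["matrix"])
    write_probeset_map(es.probeset_map, paths["map"])
    if es.dabg is not None:
        paths["dabg"] = out / "dabg.tsv"
        write_matrix(es.dabg, paths["dabg"])
    if es.design is not None:
        paths["design"] = out / "design.tsv"
        write_design(es.design, paths["design"])
    return paths


# ---------------------------------------------------------------------------
# GTF annotation I/O
# ---------------------------------------------------------------------------

def load_annotation(gtf_path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a GTF with exon and CDS features.

    Minus-strand transcripts expose exons in 5'->3' order via
    ``exons_stranded``; interval storage is ascending genomic.
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique")
    acc: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        entry = acc.setdefault(tid, {
            "gene_id": feat.attributes["gene_id"][0],
            "chrom": feat.seqid, "strand": feat.strand,
            "exons": [], "cds": []})
        key = "exons" if feat.featuretype == "exon" else "cds"
        entry[key].append((feat.start - 1, feat.end))
    models = []
    for tid in sorted(acc):
        e = acc[tid]
        models.append(TranscriptModel(
            gene_id=e["gene_id"], transcript_id=tid, chrom=e["chrom"],
            strand=e["strand"], exons=tuple(e["exons"]), cds=tuple(e["cds"])))
    models.sort(key=lambda m: (m.chrom, m.exons[0][0], m.gene_id, m.transcript_id))
    return models


def _gtf_attrs(gene_id: str, transcript_id: str | None = None) -> str:
    s = f'gene_id "{gene_id}";'
    if transcript_id is not None:
        s += f' transcript_id "{transcript_id}";'
    return s


def write_annotation(models: Sequence[TranscriptModel], gtf_path: str | Path) -> None:
    """Write models as deterministic GTF (gene/transcript/exon/CDS features)."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    lines: list[str] = []
    order = sorted(by_gene, key=lambda g: (by_gene[g][0].chrom,
                                           min(m.exons[0][0] for m in by_gene[g]), g))
    for gid in order:
        iso = sorted(by_gene[gid], key=lambda m: m.transcript_id)
        chrom, strand = iso[0].chrom, iso[0].strand
        gs = min(m.exons[0][0] for m in iso)
        ge = max(m.exons[-1][1] for m in iso)
        lines.append("\t".join([chrom, "exonsplice", "gene", str(gs + 1), str(ge),
                                ".", strand, ".", _gtf_attrs(gid)]))
        for m in iso:
            ts, te = m.exons[0][0], m.exons[-1][1]
            attrs = _gtf_attrs(gid, m.transcript_id)
            lines.append("\t".join([chrom, "exonsplice", "transcript", str(ts + 1),
                                    str(te), ".", strand, ".", attrs]))
            for a, b in m.exons:
                lines.append("\t".join([chrom, "exonsplice", "exon", str(a + 1),
                                        str(b), ".", strand, ".", attrs]))
            # GTF frame: bases to skip before the first whole codon of a segment
            consumed = 0
            frames = {}
            for a, b in m.cds_stranded:
                frames[(a, b)] = (3 - consumed % 3) % 3
                consumed += b - a
            for a, b in m.cds:
                lines.append("\t".join([chrom, "exonsplice", "CDS", str(a + 1),
                                        str(b), ".", strand, str(frames[(a, b)]),
                                        attrs]))
    Path(gtf_path).write_text("\n".join(lines) + "\n")
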