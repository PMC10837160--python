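"""Coordinate-resolved gene models: protein FASTA + BED12 + genome.

A gene model entry ties one protein accession to an ordered set of CDS
blocks on a genome assembly so that the protein sequence can be re-derived
by translation and genomic SNVs can be projected into amino-acid space.
Protein accessions that map to several candidate placements are resolved by
a deterministic preference cascade (translation-exact first, then
Met-start/in-frame, then canonical/alphanumeric chromosome, then input
order).

Coordinate conventions: BED blocks are 0-based half-open; VCF positions and
protein positions are 1-based. Blocks are stored in transcription order
(descending genomic coordinates on the minus strand).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class GeneModelError(ValueError):
    """Malformed inputs or inconsistent gene-model state."""


class CdsValidationError(GeneModelError):
    """CDS cannot be translated into a valid protein sequence."""


class RefAlleleMismatch(GeneModelError):
    """Genome base at a variant position disagrees with the VCF REF allele."""


@dataclass
class GeneModelEntry:
    """One protein accession placed on the genome.

    ``cds_blocks`` are (start, end) genomic intervals, 0-based half-open,
    in transcription order. ``validated`` is set once the CDS translation
    has been checked against ``protein_seq``.
    """

    protein_id: str
    chrom: str
    strand: str
    cds_blocks: tuple[tuple[int, int], ...]
    protein_seq: str
    is_canonical: bool = False
    bed_index: int = -1
    validated: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise GeneModelError(
                f"{self.protein_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        blocks = tuple((int(s), int(e)) for s, e in self.cds_blocks)
        for s, e in blocks:
            if e <= s:
                raise GeneModelError(f"{self.protein_id}: empty or inverted block ({s}, {e})")
        # transcription order: ascending genomic on +, descending on -
        starts = [s for s, _ in blocks]
        ordered = sorted(starts) if self.strand == "+" else sorted(starts, reverse=True)
        if starts != ordered:
            raise GeneModelError(f"{self.protein_id}: blocks not in transcription order")
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            if max(s1, s2) < min(e1, e2):
                raise GeneModelError(f"{self.protein_id}: overlapping CDS blocks")
        self.cds_blocks = blocks

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_blocks)


@dataclass(frozen=True)
class PavRecord:
    """A protein-altering variant with genomic and protein coordinates.

    ``variant_id`` is "chrom:pos:ref:alt" with a 1-based VCF position;
    ``protein_pos`` is the 1-based amino-acid index of the substitution.
    """

    variant_id: str
    protein_id: str
    protein_pos: int
    ref_aa: str
    alt_aa: str
    maf: float
    rsid: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise GeneModelError(f"{self.variant_id}: ref_aa equals alt_aa ({self.ref_aa})")
        if self.protein_pos < 1:
            raise GeneModelError(f"{self.variant_id}: protein_pos must be >= 1")
        if not (0.0 <= self.maf <= 0.5):
            raise GeneModelError(f"{self.variant_id}: MAF {self.maf} outside [0, 0.5]")

    @property
    def label(self) -> str:
        """Identifier used for isoform naming: rsID when known, else variant_id."""
        return self.rsid if self.rsid else self.variant_id


@dataclass(frozen=True)
class GenomicVariant:
    """A single-nucleotide substitution in VCF convention (1-based, plus strand)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: Optional[str] = None
    maf: float = 0.0


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Plus-strand genome slice, 0-based half-open. Accepts pyfaidx.Fasta or a mapping."""
    try:
        seq = genome[chrom]
    except KeyError as exc:
        raise GeneModelError(f"chromosome {chrom!r} absent from genome") from exc
    if start < 0 or end > len(seq):
        raise GeneModelError(
            f"block ({start}, {end}) outside {chrom} bounds (length {len(seq)})"
        )
    segment = seq[start:end]
    # pyfaidx returns a Sequence object carrying .seq
    text = segment.seq if hasattr(segment, "seq") else str(segment)
    return text.upper()


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# BED12 parsing


def _parse_bed12_line(line: str, lineno: int) -> dict:
    fields = line.rstrip("\n").split("\t")
    if len(fields) == 1:  # tolerate space-separated toy files
        fields = line.split()
    if len(fields) < 12:
        raise GeneModelError(f"BED line {lineno}: expected >=12 fields, got {len(fields)}")
    try:
        chrom = fields[0]
        chrom_start = int(fields[1])
        chrom_end = int(fields[2])
        name = fields[3]
        strand = fields[5]
        thick_start = int(fields[6])
        thick_end = int(fields[7])
        block_count = int(fields[9])
        block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except (ValueError, IndexError) as exc:
        raise GeneModelError(f"BED line {lineno}: cannot parse ({exc})") from exc
    if len(block_sizes) != block_count or len(block_starts) != block_count:
        raise GeneModelError(f"BED line {lineno}: block count mismatch")
    canonical = False
    if len(fields) > 12:
        canonical = fields[12].strip().lower() in {"1", "canonical", "yes", "true"}
    blocks = []
    for size, rel_start in zip(block_sizes, block_starts):
        b_start = chrom_start + rel_start
        b_end = b_start + size
        if b_end > chrom_end:
            raise GeneModelError(f"BED line {lineno}: block extends past chromEnd")
        # CDS = block intersected with the thick region
        s = max(b_start, thick_start)
        e = min(b_end, thick_end)
        if e > s:
            blocks.append((s, e))
    return {
        "chrom": chrom,
        "name": name,
        "strand": strand,
        "blocks": blocks,
        "canonical": canonical,
    }


def load_gene_model(
    bed_path, protein_fasta_path
) -> tuple[dict[str, list[GeneModelEntry]], list[str]]:
    """Join a BED12 annotation track with a protein FASTA.

    Returns ``(candidates, unmapped)``: candidate entries grouped per
    protein_id (a protein may have several genomic placements), and the list
    of FASTA accessions with no BED record. BED names absent from the FASTA
    are logged and skipped; duplicate FASTA identifiers are an error.
    """
    proteins: dict[str, str] = {}
    for rec in SeqIO.parse(str(protein_fasta_path), "fasta"):
        if rec.id in proteins:
            raise GeneModelError(f"duplicate FASTA identifier {rec.id!r}")
        proteins[rec.id] = str(rec.seq).upper()

    candidates: dict[str, list[GeneModelEntry]] = {}
    bed_index = 0
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            rec = _parse_bed12_line(line, lineno)
            if rec["name"] not in proteins:
                logger.warning(
                    "BED line %d: protein %r absent from FASTA, skipped", lineno, rec["name"]
                )
                continue
            blocks = rec["blocks"]
            if rec["strand"] == "-":
                blocks = list(reversed(blocks))
            entry = GeneModelEntry(
                protein_id=rec["name"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                cds_blocks=tuple(blocks),
                protein_seq=proteins[rec["name"]],
                is_canonical=rec["canonical"],
                bed_index=bed_index,
            )
            candidates.setdefault(rec["name"], []).append(entry)
            bed_index += 1
    unmapped = sorted(set(proteins) - set(candidates))
    return candidates, unmapped


# ---------------------------------------------------------------------------
# Translation


def cds_sequence(entry: GeneModelEntry, genome) -> str:
    """Spliced CDS nucleotide sequence in reading-frame orientation."""
    parts = []
    for s, e in entry.cds_blocks:
        block = _fetch(genome, entry.chrom, s, e)
        parts.append(_revcomp(block) if entry.strand == "-" else block)
    return "".join(parts)


def translate_cds(entry: GeneModelEntry, genome) -> str:
    """Translate the entry's CDS with the standard codon table.

    A single trailing stop codon is trimmed silently; an internal stop or a
    CDS length not divisible by three raises :class:`CdsValidationError`.
    """
    cds = cds_sequence(entry, genome)
    if len(cds) % 3 != 0:
        raise CdsValidationError(
            f"{entry.protein_id}: CDS length {len(cds)} not a multiple of 3"
        )
    aa = str(Seq(cds).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise CdsValidationError(f"{entry.protein_id}: internal stop codon in CDS")
    return aa


def validate_entry(entry: GeneModelEntry, genome) -> bool:
    """True iff the CDS translation reproduces ``protein_seq`` exactly."""
    try:
        return translate_cds(entry, genome) == entry.protein_seq
    except GeneModelError:
        return False


# ---------------------------------------------------------------------------
# Ambiguity resolution


def resolve_ambiguous_mappings(
    candidates: Mapping[str, Sequence[GeneModelEntry]], genome
) -> tuple[list[GeneModelEntry], dict[str, str]]:
    """Select one placement per protein_id by the preference cascade.

    1. a unique candidate is kept as-is;
    2. among several, prefer placements whose CDS translation equals the
       FASTA sequence exactly;
    3. failing that, prefer in-frame placements whose translation starts
       with Met;
    4. across chromosomes, prefer canonical placements, then the
       alphanumerically first chromosome;
    5. remaining ties are broken by input (BED) order.

    Returns the resolved entries plus a reason string for every excluded
    protein_id.
    """
    resolved: list[GeneModelEntry] = []
    excluded: dict[str, str] = {}
    for pid, cands in candidates.items():
        cands = sorted(cands, key=lambda c: c.bed_index)
        if len(cands) == 1:
            entry = cands[0]
            entry.validated = validate_entry(entry, genome)
            resolved.append(entry)
            continue

        translations: dict[int, Optional[str]] = {}
        for c in cands:
            try:
                translations[c.bed_index] = translate_cds(c, genome)
            except GeneModelError:
                translations[c.bed_index] = None
        usable = [c for c in cands if translations[c.bed_index] is not None]
        if not usable:
            excluded[pid] = "no candidate has a translatable CDS"
            logger.warning("%s excluded: %s", pid, excluded[pid])
            continue

        exact = [c for c in usable if translations[c.bed_index] == c.protein_seq]
        pool = exact
        if not pool:
            pool = [
                c
                for c in usable
                if translations[c.bed_index] and translations[c.bed_index].startswith("M")
            ]
        if not pool:
            pool = usable

        chroms = {c.chrom for c in pool}
        if len(chroms) > 1:
            canonical = [c for c in pool if c.is_canonical]
            if canonical:
                pool = canonical
            if len({c.chrom for c in pool}) > 1:
                first_chrom = min(c.chrom for c in pool)
                pool = [c for c in pool if c.chrom == first_chrom]
        # within one chromosome: first in BED order (also covers multiple canonical)
        entry = min(pool, key=lambda c: c.bed_index)
        entry.validated = validate_entry(entry, genome)
        resolved.append(entry)
    return resolved, excluded


# ---------------------------------------------------------------------------
# Variant consequence mapping


def _cds_index_of(entry: GeneModelEntry, pos0: int) -> Optional[int]:
    """0-based CDS coordinate of a 0-based genomic position, or None."""
    offset = 0
    for s, e in entry.cds_blocks:
        if s <= pos0 < e:
            if entry.strand == "+":
                return offset + (pos0 - s)
            return offset + (e - 1 - pos0)
        offset += e - s
    return None


def codon_genomic_positions(entry: GeneModelEntry, protein_pos: int) -> tuple[int, int, int]:
    """1-based genomic positions of the three codon bases, in codon order."""
    if not (1 <= protein_pos <= entry.cds_length // 3):
        raise GeneModelError(f"{entry.protein_id}: protein_pos {protein_pos} out of CDS")
    wanted = range((protein_pos - 1) * 3, (protein_pos - 1) * 3 + 3)
    positions = []
    offset = 0
    for s, e in entry.cds_blocks:
        length = e - s
        for cds_i in wanted:
            if offset <= cds_i < offset + length:
                if entry.strand == "+":
                    positions.append(s + (cds_i - offset) + 1)
                else:
                    positions.append(e - (cds_i - offset))
        offset += length
    positions_by_codon = sorted(
        positions, reverse=(entry.strand == "-")
    )
    return tuple(positions_by_codon)  # type: ignore[return-value]


def map_variant_to_protein(
    variant: GenomicVariant, entry: GeneModelEntry, genome
) -> Optional[PavRecord]:
    """Project a genomic SNV onto the protein; missense only.

    Returns a :class:`PavRecord` iff the variant lies in a CDS block and
    substitutes the encoded residue for a different amino acid. Synonymous,
    stop-gain, stop-loss and non-coding positions return ``None``. A genome
    base that contradicts the VCF REF allele raises
    :class:`RefAlleleMismatch`.
    """
    if variant.chrom != entry.chrom:
        return None
    if len(variant.ref) != 1 or len(variant.alt) != 1:
        return None
    pos0 = variant.pos - 1
    cds_i = _cds_index_of(entry, pos0)
    if cds_i is None:
        return None
    genome_base = _fetch(genome, variant.chrom, pos0, pos0 + 1)
    if genome_base != variant.ref.upper():
        raise RefAlleleMismatch(
            f"{variant.chrom}:{variant.pos}: genome has {genome_base}, VCF REF is {variant.ref}"
        )
    codon_i, within = divmod(cds_i, 3)
    cds = cds_sequence(entry, genome)
    ref_codon = cds[codon_i * 3 : codon_i * 3 + 3]
    alt_base = variant.alt.upper()
    if entry.strand == "-":
        alt_base = alt_base.translate(_COMPLEMENT)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if codon_i >= len(entry.protein_seq):
        return None  # inside the trailing stop codon
    if ref_aa == alt_aa or "*" in (ref_aa, alt_aa):
        return None
    if entry.protein_seq[codon_i] != ref_aa:
        logger.warning(
            "%s: translated residue %s at position %d disagrees with protein sequence %s; "
            "variant %s skipped",
            entry.protein_id,
            ref_aa,
            codon_i + 1,
            entry.protein_seq[codon_i],
            variant,
        )
        return None
    return PavRecord(
        variant_id=f"{variant.chrom}:{variant.pos}:{variant.ref.upper()}:{variant.alt.upper()}",
        protein_id=entry.protein_id,
        protein_pos=codon_i + 1,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        maf=variant.maf,
        rsid=variant.rsid,
    )


def pavs_from_vcf(
    vcf_path, entries: Iterable[GeneModelEntry], genome
) -> tuple[list[PavRecord], list[tuple[str, str]]]:
    """Scan a VCF for missense SNVs against the resolved gene model.

    MAF is taken from the sample genotypes (folded alternate-allele
    frequency). Variants whose REF disagrees with the genome are skipped and
    reported in the second return value as (variant, reason) pairs.
    """
    from cyvcf2 import VCF  # deferred: cyvcf2 import is comparatively heavy

    by_chrom: dict[str, list[GeneModelEntry]] = {}
    for e in entries:
        by_chrom.setdefault(e.chrom, []).append(e)
    pavs: list[PavRecord] = []
    skipped: list[tuple[str, str]] = []
    for v in VCF(str(vcf_path)):
        if v.CHROM not in by_chrom:
            continue
        for alt in v.ALT:
            if len(v.REF) != 1 or len(alt) != 1:
                continue
            aaf = float(v.aaf) if v.aaf is not None else 0.0
            variant = GenomicVariant(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=alt,
                rsid=v.ID if v.ID not in (None, ".") else None,
                maf=min(aaf, 1.0 - aaf),
            )
            for entry in by_chrom[v.CHROM]:
                try:
                    rec = map_variant_to_protein(variant, entry, genome)
                except RefAlleleMismatch as exc:
                    skipped.append((f"{v.CHROM}:{v.POS}:{v.REF}:{alt}", str(exc)))
                    continue
                if rec is not None:
                    pavs.append(rec)
    return pavs, skipped


# ---------------------------------------------------------------------------
# Serialization


def save_model(entries: Iterable[GeneModelEntry], path) -> None:
    """TSV with one row per protein; CDS blocks JSON-encoded in transcription order."""
    rows = [
        {
            "protein_id": e.protein_id,
            "chrom": e.chrom,
            "strand": e.strand,
            "cds_blocks": json.dumps([list(b) for b in e.cds_blocks]),
            "protein_seq": e.protein_seq,
            "is_canonical": int(e.is_canonical),
            "validated": "" if e.validated is None else int(e.validated),
        }
        for e in entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_model(path) -> list[GeneModelEntry]:
    df = pd.read_csv(path, sep="\t", dtype={"validated": "object"})
    entries = []
    for i, row in df.iterrows():
        validated = row.get("validated")
        entries.append(
            GeneModelEntry(
                protein_id=row["protein_id"],
                chrom=str(row["chrom"]),
                strand=row["strand"],
                cds_blocks=tuple(tuple(b) for b in json.loads(row["cds_blocks"])),
                protein_seq=row["protein_seq"],
                is_canonical=bool(int(row.get("is_canonical", 0))),
                bed_index=int(i),
                validated=None if pd.isna(validated) or validated == "" else bool(int(validated)),
            )
        )
    return entries
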