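"""Variant injection, in-silico tryptic digestion, and the three peptide libraries.

Protein-altering variants above the minor-allele-frequency cutoff are
injected one at a time into the reference protein sequence; both sequences
are digested with trypsin rules (cleave after K/R, no proline exception, up
to one missed cleavage, 7-30 aa, optional N-terminal Met excision); and the
digests are matched position-wise to classify alternate peptides as
``simple`` (same start, same length, different sequence), ``complex``
(unpaired, cleavage pattern unchanged) or ``discarded`` (unpaired because
the substitution created or removed a K/R cleavage site).

Three libraries result: *reference* (reference-allele peptides only, the
standard DIA search space), *PAV-inclusive* (reference plus simple-match
alternate peptides, with one injected isoform protein entry per variant),
and *PAV-exclusive* (reference minus every variant-overlapping peptide,
used for genotype-independent protein quantification).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .gene_model import GeneModelEntry, PavRecord, STANDARD_AA

logger = logging.getLogger(__name__)

ORIGIN_INVARIANT = "invariant"
ORIGIN_REF = "ref_allele"
ORIGIN_ALT = "alt_allele"


class LibraryError(ValueError):
    pass


@dataclass(frozen=True)
class PeptideEntry:
    """A digested peptide form.

    ``start_pos`` is the 1-based position of the peptide's first residue in
    its source sequence (reference or injected); ``met_excised`` marks the
    N-terminal-Met-removed form; ``origin`` records whether the peptide
    overlaps a variant position and on which allele background.
    """

    sequence: str
    protein_id: str
    start_pos: int
    missed_cleavages: int
    met_excised: bool = False
    origin: str = ORIGIN_INVARIANT
    variant_id: Optional[str] = None
    match_class: str = "n/a"

    def overlaps(self, protein_pos: int) -> bool:
        return self.start_pos <= protein_pos <= self.start_pos + len(self.sequence) - 1


@dataclass
class MatchedPair:
    ref: Optional[PeptideEntry]
    alt: Optional[PeptideEntry]
    match_class: str  # simple | complex | discarded


@dataclass
class LibrarySet:
    """The three peptide libraries plus isoform FASTA entries and provenance."""

    reference: list[PeptideEntry]
    pav_inclusive: list[PeptideEntry]
    pav_exclusive: list[PeptideEntry]
    isoforms: dict[str, str] = field(default_factory=dict)
    matches: list[MatchedPair] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def annotation_frame(self) -> pd.DataFrame:
        """One row per PAV-inclusive library entry; the join key for reports."""
        rows = [
            {
                "sequence": p.sequence,
                "protein_id": p.protein_id,
                "start_pos": p.start_pos,
                "missed_cleavages": p.missed_cleavages,
                "met_excised": p.met_excised,
                "origin": p.origin,
                "variant_id": p.variant_id,
                "match_class": p.match_class,
            }
            for p in self.pav_inclusive
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "sequence",
                "protein_id",
                "start_pos",
                "missed_cleavages",
                "met_excised",
                "origin",
                "variant_id",
                "match_class",
            ],
        )

    def peptide_frame(self, library: str) -> pd.DataFrame:
        peptides = getattr(self, library)
        return pd.DataFrame(
            [
                {
                    "sequence": p.sequence,
                    "protein_id": p.protein_id,
                    "start_pos": p.start_pos,
                    "missed_cleavages": p.missed_cleavages,
                    "origin": p.origin,
                    "variant_id": p.variant_id,
                    "match_class": p.match_class,
                }
                for p in peptides
            ]
        )


# ---------------------------------------------------------------------------


def filter_pavs_by_maf(
    pavs: Iterable[PavRecord], threshold: float = 0.10
) -> list[PavRecord]:
    """Keep variants with MAF strictly above ``threshold`` (default 10%)."""
    kept = []
    for pav in pavs:
        if not (0.0 <= pav.maf <= 0.5):
            raise LibraryError(f"{pav.variant_id}: MAF {pav.maf} outside [0, 0.5]")
        if pav.maf > threshold:
            kept.append(pav)
    return kept


def inject_variant(protein_seq: str, pav: PavRecord) -> str:
    """Substitute ``alt_aa`` at the variant position; length is unchanged."""
    idx = pav.protein_pos - 1
    if idx >= len(protein_seq):
        raise LibraryError(
            f"{pav.variant_id}: position {pav.protein_pos} beyond {pav.protein_id} "
            f"(length {len(protein_seq)})"
        )
    if protein_seq[idx] != pav.ref_aa:
        raise LibraryError(
            f"{pav.variant_id}: reference residue mismatch in {pav.protein_id} at "
            f"{pav.protein_pos}: sequence has {protein_seq[idx]}, variant expects {pav.ref_aa}"
        )
    return protein_seq[:idx] + pav.alt_aa + protein_seq[idx + 1 :]


def digest(
    protein_seq: str,
    protein_id: str = "",
    min_len: int = 7,
    max_len: int = 30,
    max_missed: int = 1,
    met_excision: bool = True,
) -> list[PeptideEntry]:
    """Tryptic in-silico digest.

    Cleaves strictly after every K or R (no proline exception, matching the
    ``--cut K*,R*`` search convention), enumerates 0..``max_missed`` missed
    cleavages, applies the length window afterwards, and — when the protein
    starts with Met — additionally emits protein-N-terminal peptides with
    the Met removed (``--met-excision`` behaviour).
    """
    bad = sorted(set(protein_seq) - STANDARD_AA)
    if bad:
        raise LibraryError(f"non-standard residues in sequence: {''.join(bad)}")
    if not protein_seq:
        raise LibraryError("empty protein sequence")

    # fragment boundaries: cut after every K/R
    cuts = [0] + [i + 1 for i, aa in enumerate(protein_seq) if aa in "KR"]
    if cuts[-1] != len(protein_seq):
        cuts.append(len(protein_seq))
    fragments = list(zip(cuts, cuts[1:]))

    out: list[PeptideEntry] = []
    for mc in range(max_missed + 1):
        for i in range(len(fragments) - mc):
            start = fragments[i][0]
            end = fragments[i + mc][1]
            candidates = [(start, protein_seq[start:end], False)]
            if met_excision and start == 0 and protein_seq[0] == "M":
                candidates.append((1, protein_seq[1:end], True))
            for s, pep, excised in candidates:
                if min_len <= len(pep) <= max_len:
                    out.append(
                        PeptideEntry(
                            sequence=pep,
                            protein_id=protein_id,
                            start_pos=s + 1,
                            missed_cleavages=mc,
                            met_excised=excised,
                        )
                    )
    return out


def match_peptides(
    ref_digest: Sequence[PeptideEntry],
    alt_digest: Sequence[PeptideEntry],
    pav: PavRecord,
) -> list[MatchedPair]:
    """Pair variant-overlapping reference and alternate peptides.

    Matching is performed separately per missed-cleavage count (and Met
    excision state): an alternate peptide pairs ``simple`` with the
    reference peptide of equal start and equal length whose sequence
    differs. Unpaired alternates caused by K/R gain or loss are
    ``discarded``; other unpaired alternates are ``complex``. Peptides not
    covering the variant position are invariant and excluded from pairing.
    """
    pos = pav.protein_pos
    ref_over = [p for p in ref_digest if p.overlaps(pos)]
    alt_over = [p for p in alt_digest if p.overlaps(pos)]
    if not ref_over:
        logger.warning(
            "%s: variant position %d not covered by any reference peptide "
            "(undetectable region)",
            pav.variant_id,
            pos,
        )
        return []

    kr_change = (pav.ref_aa in "KR") != (pav.alt_aa in "KR")
    by_key = {
        (p.start_pos, len(p.sequence), p.missed_cleavages, p.met_excised): p for p in ref_over
    }
    pairs: list[MatchedPair] = []
    matched_ref_keys = set()
    for alt in alt_over:
        key = (alt.start_pos, len(alt.sequence), alt.missed_cleavages, alt.met_excised)
        ref = by_key.get(key)
        if ref is not None and ref.sequence != alt.sequence:
            pairs.append(MatchedPair(ref=ref, alt=alt, match_class="simple"))
            matched_ref_keys.add(key)
        else:
            pairs.append(
                MatchedPair(ref=None, alt=alt, match_class="discarded" if kr_change else "complex")
            )
    for key, ref in by_key.items():
        if key not in matched_ref_keys:
            pairs.append(
                MatchedPair(ref=ref, alt=None, match_class="discarded" if kr_change else "complex")
            )
    return pairs


def _protein_sequences(
    gene_model: Union[Mapping[str, str], Iterable[GeneModelEntry]]
) -> dict[str, str]:
    if isinstance(gene_model, Mapping):
        return dict(gene_model)
    return {e.protein_id: e.protein_seq for e in gene_model}


def build_libraries(
    gene_model: Union[Mapping[str, str], Iterable[GeneModelEntry]],
    pavs: Sequence[PavRecord],
    min_len: int = 7,
    max_len: int = 30,
    max_missed: int = 1,
    met_excision: bool = True,
) -> LibrarySet:
    """Digest the proteome and assemble the three libraries.

    Variants are treated independently — each is injected into the pure
    reference background, one substitution per isoform entry (named
    ``{protein_id}_{rsID}``, falling back to the chrom:pos:ref:alt id).
    ``pavs`` are expected to be MAF-filtered already.
    """
    proteins = _protein_sequences(gene_model)
    seen_ids = set()
    for pav in pavs:
        if pav.variant_id in seen_ids:
            raise LibraryError(f"duplicate variant_id {pav.variant_id}")
        seen_ids.add(pav.variant_id)

    digest_kw = dict(
        min_len=min_len, max_len=max_len, max_missed=max_missed, met_excision=met_excision
    )
    ref_digests = {pid: digest(seq, pid, **digest_kw) for pid, seq in proteins.items()}

    pavs_by_protein: dict[str, list[PavRecord]] = {}
    for pav in pavs:
        if pav.protein_id not in proteins:
            raise LibraryError(f"{pav.variant_id}: protein {pav.protein_id} not in gene model")
        pavs_by_protein.setdefault(pav.protein_id, []).append(pav)

    # reference library: annotate variant-overlapping peptides per variant
    reference: list[PeptideEntry] = []
    for pid, peptides in ref_digests.items():
        for p in peptides:
            overlapping = [v for v in pavs_by_protein.get(pid, []) if p.overlaps(v.protein_pos)]
            if not overlapping:
                reference.append(p)
            else:
                for v in overlapping:
                    reference.append(
                        replace(p, origin=ORIGIN_REF, variant_id=v.variant_id)
                    )

    pav_inclusive = list(reference)
    isoforms: dict[str, str] = {}
    all_matches: list[MatchedPair] = []
    for pav in pavs:
        seq = proteins[pav.protein_id]
        alt_seq = inject_variant(seq, pav)
        alt_digest = digest(alt_seq, pav.protein_id, **digest_kw)
        pairs = match_peptides(ref_digests[pav.protein_id], alt_digest, pav)
        isoforms[f"{pav.protein_id}_{pav.label}"] = alt_seq
        for pair in pairs:
            if pair.alt is not None:
                pair.alt = replace(
                    pair.alt,
                    origin=ORIGIN_ALT,
                    variant_id=pav.variant_id,
                    match_class=pair.match_class,
                )
            if pair.ref is not None:
                pair.ref = replace(
                    pair.ref,
                    origin=ORIGIN_REF,
                    variant_id=pav.variant_id,
                    match_class=pair.match_class,
                )
            if pair.match_class == "simple" and pair.alt is not None:
                pav_inclusive.append(pair.alt)
        all_matches.extend(pairs)

    pav_exclusive = [p for p in reference if p.origin == ORIGIN_INVARIANT]

    return LibrarySet(
        reference=reference,
        pav_inclusive=pav_inclusive,
        pav_exclusive=pav_exclusive,
        isoforms=isoforms,
        matches=all_matches,
        provenance={
            "n_proteins": len(proteins),
            "n_pavs": len(pavs),
            "n_reference": len(reference),
            "n_pav_inclusive": len(pav_inclusive),
            "n_pav_exclusive": len(pav_exclusive),
            "digest": digest_kw,
        },
    )


def write_library_fasta(library: LibrarySet, proteins: Mapping[str, str], out_dir) -> None:
    """Per-library FASTA files; isoform entries are separate records."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "reference.fasta", "w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid}\n{seq}\n")
    with open(out / "pav_inclusive.fasta", "w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid}\n{seq}\n")
        for name, seq in library.isoforms.items():
            fh.write(f">{name}\n{seq}\n")
    # exclusive library is peptide-level; FASTA mirrors the reference proteome
    with open(out / "pav_exclusive.fasta", "w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid}\n{seq}\n")
    for lib in ("reference", "pav_inclusive", "pav_exclusive"):
        library.peptide_frame(lib).to_csv(out / f"{lib}.peptides.tsv", sep="\t", index=False)
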