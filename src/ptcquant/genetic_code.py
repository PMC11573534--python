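"""Genetic-code machinery for stop-codon readthrough.

Translation termination competes with decoding of the stop codon by
near-cognate tRNAs, whose anticodons pair with only two of the three codon
bases. This module enumerates the near-cognate decoding candidates of each
stop codon (every sense codon at Hamming distance 1) and ranks them by the
stability argument for aminoglycoside-induced readthrough: a candidate whose
cognate codon carries C at position 1 presents a 3' G in the tRNA anticodon
opposite the stop codon's 5' U, forming the comparatively stable G:U wobble
pair. That single wobble-stabilized candidate per stop codon (R for TGA via
CGA; Q for TAA via CAA; Q for TAG via CAG) is the expected dominant
incorporation.

Sequences are handled in DNA alphabet internally; RNA input (U) is accepted
and normalized to T. Codon positions are 1-based 5'->3'; the anticodon runs
3'->5' so codon position 1 pairs with anticodon position 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio.Data import CodonTable

from .errors import InputError

STOP = "*"
BASES = "ACGT"
PURINES = frozenset("AG")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def normalize_nt(seq: str) -> str:
    """Uppercase a nucleotide string and map RNA U to DNA T.

    Raises :class:`InputError` on characters outside {A, C, G, T, U}.
    """
    out = seq.upper().replace("U", "T")
    bad = set(out) - set(BASES)
    if bad:
        raise InputError(f"non-ACGTU characters in sequence: {sorted(bad)}")
    return out


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid table with an explicit stop-codon set."""

    codon_to_aa: Mapping[str, str]
    stop_codons: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise InputError("genetic code must map exactly 64 codons")
        stops = {c for c, aa in self.codon_to_aa.items() if aa == STOP}
        if stops != set(self.stop_codons):
            raise InputError("stop_codons inconsistent with codon table")

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The standard nuclear genetic code, from Biopython's codon table."""
        table = CodonTable.unambiguous_dna_by_id[1]
        mapping = dict(table.forward_table)
        for codon in table.stop_codons:
            mapping[codon] = STOP
        return cls(codon_to_aa=mapping, stop_codons=frozenset(table.stop_codons))

    def aa(self, codon: str) -> str:
        codon = normalize_nt(codon)
        if len(codon) != 3:
            raise InputError(f"codon must have length 3, got {codon!r}")
        return self.codon_to_aa[codon]

    def codons_for(self, amino_acid: str) -> list[str]:
        return sorted(c for c, aa in self.codon_to_aa.items() if aa == amino_acid)


STANDARD_CODE = GeneticCode.standard()


@dataclass(frozen=True)
class TranslationResult:
    """Protein product of one reading frame.

    ``stop_codon_index`` is the 1-based codon number of the terminating stop
    codon (``None`` when translation ran off the end of the sequence without
    meeting a stop, in which case ``ran_off_end`` is set instead of raising).
    """

    protein: str
    stop_codon_index: int | None
    ran_off_end: bool = False


def translate(cds: str, code: GeneticCode = STANDARD_CODE) -> TranslationResult:
    """Translate from position 1 of the given frame up to the first stop.

    The stop codon itself is excluded from the product. A trailing partial
    codon is ignored.
    """
    cds = normalize_nt(cds)
    if len(cds) < 3:
        raise InputError("coding sequence shorter than one codon")
    residues: list[str] = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = code.codon_to_aa[cds[i : i + 3]]
        if aa == STOP:
            return TranslationResult("".join(residues), stop_codon_index=i // 3 + 1)
        residues.append(aa)
    return TranslationResult("".join(residues), stop_codon_index=None, ran_off_end=True)


@dataclass(frozen=True)
class CandidateIncorporation:
    """One near-cognate decoding candidate of a stop codon.

    ``cognate_codon`` is the sense codon at Hamming distance 1 whose tRNA can
    mis-decode the stop; ``mismatch_position`` is the codon position (1..3,
    5'->3') at which it differs. ``wobble_stabilized`` is true iff the
    mismatch is at position 1 and the cognate codon has C there, so the
    anticodon presents a 3' G opposite the codon's 5' U.
    """

    amino_acid: str
    cognate_codon: str
    mismatch_position: int
    wobble_stabilized: bool


def _require_stop(stop_codon: str, code: GeneticCode) -> str:
    stop_codon = normalize_nt(stop_codon)
    if stop_codon not in code.stop_codons:
        raise InputError(f"{stop_codon!r} is not a stop codon")
    return stop_codon


def near_cognate_candidates(
    stop_codon: str,
    code: GeneticCode = STANDARD_CODE,
    include_selenocysteine: bool = False,
) -> list[CandidateIncorporation]:
    """All near-cognate decoding candidates of a stop codon.

    One entry per non-stop codon at Hamming distance 1 from the stop codon,
    sorted by (amino acid, codon). Selenocysteine decoding of TGA (a cognate,
    not near-cognate, event mediated by tRNA[Ser]Sec) is off by default and
    may be enabled with ``include_selenocysteine``.
    """
    stop_codon = _require_stop(stop_codon, code)
    out: list[CandidateIncorporation] = []
    for pos in range(3):
        for base in BASES:
            if base == stop_codon[pos]:
                continue
            codon = stop_codon[:pos] + base + stop_codon[pos + 1 :]
            aa = code.codon_to_aa[codon]
            if aa == STOP:
                continue
            out.append(
                CandidateIncorporation(
                    amino_acid=aa,
                    cognate_codon=codon,
                    mismatch_position=pos + 1,
                    wobble_stabilized=(pos == 0 and codon[0] == "C"),
                )
            )
    if include_selenocysteine and stop_codon == "TGA":
        out.append(CandidateIncorporation("U", "TGA", 0, False))
    return sorted(out, key=lambda c: (c.amino_acid, c.cognate_codon))


def _pair_tier(candidate: CandidateIncorporation, stop_codon: str) -> int:
    """Rank tier of one candidate codon under the wobble-stability heuristic.

    0: G:U wobble at position 1 (anticodon 3' G opposite codon 5' U);
    1: any other purine-pyrimidine mismatch at position 1;
    2: position-3 mismatch; 3: position-2 mismatch;
    4: pyrimidine-pyrimidine (or purine-purine) mismatch at position 1.
    """
    pos = candidate.mismatch_position
    if candidate.wobble_stabilized:
        return 0
    if pos == 1:
        anticodon_base = COMPLEMENT[candidate.cognate_codon[0]]
        stop_base = stop_codon[0]
        if (anticodon_base in PURINES) != (stop_base in PURINES):
            return 1
        return 4
    return 2 if pos == 3 else 3


@dataclass(frozen=True)
class RankedCandidate:
    amino_acid: str
    tier: int
    codons: tuple[str, ...]


#: Human-readable record of the ranking heuristic, serialized with results.
RANKING_SCHEME = (
    "tier0: G:U wobble (position-1 mismatch, cognate codon C1, anticodon 3'G); "
    "tier1: other purine-pyrimidine position-1 mismatch; "
    "tier2: position-3 mismatch; tier3: position-2 mismatch; "
    "tier4: pyrimidine-pyrimidine position-1 mismatch; "
    "ties broken alphabetically"
)


@dataclass(frozen=True)
class DominanceRanking:
    """Ranked amino-acid incorporation expectation for one stop codon."""

    stop_codon: str
    ranked: tuple[RankedCandidate, ...]
    scheme: str = field(default=RANKING_SCHEME)

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(r.amino_acid for r in self.ranked)


def predict_dominance_order(
    stop_codon: str, code: GeneticCode = STANDARD_CODE
) -> DominanceRanking:
    """Rank near-cognate candidates by expected incorporation dominance.

    Only the top of the order (the single wobble-stabilized candidate) is
    anchored in the stability argument; the remaining tiers are a declared
    heuristic (purine-pyrimidine over pyrimidine-pyrimidine; position order
    1, 3, 2) recorded in ``scheme``.
    """
    stop_codon = _require_stop(stop_codon, code)
    candidates = near_cognate_candidates(stop_codon, code)
    by_aa: dict[str, list[CandidateIncorporation]] = {}
    for cand in candidates:
        by_aa.setdefault(cand.amino_acid, []).append(cand)
    ranked = [
        RankedCandidate(
            amino_acid=aa,
            tier=min(_pair_tier(c, stop_codon) for c in group),
            codons=tuple(c.cognate_codon for c in group),
        )
        for aa, group in by_aa.items()
    ]
    ranked.sort(key=lambda r: (r.tier, r.amino_acid))
    return DominanceRanking(stop_codon=stop_codon, ranked=tuple(ranked))


def candidate_table(rankings: Iterable[DominanceRanking]) -> str:
    """Tab-separated export of one or more dominance rankings."""
    lines = ["stop_codon\trank\tamino_acid\ttier\tcodons\twobble_stabilized"]
    for ranking in rankings:
        wobble = {
            c.amino_acid
            for c in near_cognate_candidates(ranking.stop_codon)
            if c.wobble_stabilized
        }
        for i, rc in enumerate(ranking.ranked, start=1):
            lines.append(
                f"{ranking.stop_codon}\t{i}\t{rc.amino_acid}\t{rc.tier}\t"
                f"{','.join(rc.codons)}\t{rc.amino_acid in wobble}"
            )
    return "\n".join(lines) + "\n"
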