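"""Readthrough proteoform enumeration and FASTA database construction.

A :class:`CodingConstruct` holds a CDS from the initiator ATG *through and
beyond* its stop codons, so that products which translate past a stop
(substitution readthrough, stop-skip, frameshift) can be extended to the next
in-frame termination codon. Declared :class:`StopCodonSite` entries mark the
premature (or terminal) stop codons of interest.

Three event classes are enumerated:

* substitution readthrough — the stop codon decoded by a (near-)cognate tRNA,
  one proteoform per candidate amino acid, full length preserved;
* stop-skip — the stop triplet bypassed with the frame preserved (modeled as
  deletion of the 3-nt triplet), extending translation to the next in-frame
  stop;
* frameshift(k) — translation resumes k bases after the 3' end of the stop
  triplet, in the shifted frame, to the next stop in that frame.

Every proteoform records the nucleotide sequence it was generated from, so
its amino-acid sequence can be re-derived by translation (a nucleotide-level
oracle used by the test-suite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError, ValidationError
from .genetic_code import STANDARD_CODE, GeneticCode, normalize_nt, translate

DEFAULT_FRAMESHIFTS = (1, 2, 4, 7, 8, 10, 19)
ALL_AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class StopCodonSite:
    """A stop codon at a 1-based codon index counted from the initiator ATG."""

    codon_index: int
    triplet: str
    label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "triplet", normalize_nt(self.triplet))
        if self.codon_index < 1:
            raise ValidationError("codon_index must be >= 1")
        if len(self.triplet) != 3:
            raise ValidationError("site triplet must have length 3")


@dataclass(frozen=True)
class CodingConstruct:
    """A named CDS (plus downstream sequence) with declared stop-codon sites."""

    name: str
    cds: str
    sites: tuple[StopCodonSite, ...] = ()
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cds", normalize_nt(self.cds))
        object.__setattr__(self, "sites", tuple(self.sites))
        if not self.cds.startswith("ATG"):
            raise ValidationError(f"{self.name}: CDS does not start with ATG")
        for site in self.sites:
            if self.codon(site.codon_index) != site.triplet:
                raise ValidationError(
                    f"{self.name}: codon {site.codon_index} is "
                    f"{self.codon(site.codon_index)!r}, site declares {site.triplet!r}"
                )
            if site.triplet not in STANDARD_CODE.stop_codons:
                raise ValidationError(
                    f"{self.name}: site {site.label} triplet {site.triplet!r} "
                    "is not a stop codon"
                )

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    def codon(self, index: int) -> str:
        """The codon at 1-based index ``index``."""
        if not 1 <= index <= self.n_codons:
            raise InputError(f"codon index {index} outside CDS (1..{self.n_codons})")
        return self.cds[3 * (index - 1) : 3 * index]

    def site(self, label: str) -> StopCodonSite:
        for s in self.sites:
            if s.label == label:
                return s
        raise InputError(f"{self.name}: no declared site labelled {label!r}")


@dataclass(frozen=True)
class Proteoform:
    """One readthrough protein product with its provenance.

    ``event`` is one of ``"sub"`` (substitution readthrough), ``"skip"``
    (stop-skip) or ``"fs"`` (frameshift, with ``shift_k`` set). ``cds`` is
    the generating nucleotide sequence (excluded from equality; it is
    provenance, not identity, and is lost on FASTA round-trips).
    """

    id: str
    sequence: str
    event: str
    site_label: str
    incorporated: str | None = None
    shift_k: int | None = None
    cds: str | None = field(default=None, compare=False)
    ran_off_end: bool = field(default=False, compare=False)
    zero_length_extension: bool = field(default=False, compare=False)

    @property
    def variant(self) -> str:
        """Short variant key: the incorporated residue, or the event name."""
        if self.event == "sub":
            return self.incorporated or "?"
        if self.event == "fs":
            return f"fs{self.shift_k}"
        return self.event


def apply_codon_edits(
    construct: CodingConstruct, edits: Sequence[tuple[int, str]]
) -> CodingConstruct:
    """Return a new construct with codons replaced; the original is untouched.

    Editing a declared stop site into a sense codon raises
    :class:`ValidationError` (update or drop the site declaration instead);
    editing it into another stop codon updates the site's triplet.
    """
    cds = list(construct.cds)
    sites = {s.codon_index: s for s in construct.sites}
    for index, triplet in edits:
        triplet = normalize_nt(triplet)
        if len(triplet) != 3:
            raise InputError(f"edit at codon {index}: triplet must have length 3")
        construct.codon(index)  # bounds check
        if index in sites:
            if triplet not in STANDARD_CODE.stop_codons:
                raise ValidationError(
                    f"edit at codon {index} turns declared stop site "
                    f"{sites[index].label!r} into a sense codon; "
                    "update the site declarations"
                )
            sites[index] = replace(sites[index], triplet=triplet)
        cds[3 * (index - 1) : 3 * index] = triplet
    edit_log = list(construct.metadata.get("edits", [])) + [
        f"{i}:{construct.codon(i)}>{normalize_nt(t)}" for i, t in edits
    ]
    name = construct.name if not edits else f"{construct.name}+{len(edit_log)}edits"
    return CodingConstruct(
        name=name,
        cds="".join(cds),
        sites=tuple(sites[i] for i in sorted(sites)),
        metadata={**construct.metadata, "edits": edit_log},
    )


def _pick_codon(amino_acid: str, stop_triplet: str, code: GeneticCode) -> str:
    """Codon used to realize a substitution at nucleotide level.

    Prefers the alphabetically first codon at Hamming distance 1 from the
    stop triplet (the near-cognate codon), falling back to the alphabetically
    first codon of the amino acid.
    """
    codons = code.codons_for(amino_acid)
    if not codons:
        raise InputError(f"no codon encodes {amino_acid!r}")
    near = [
        c for c in codons if sum(a != b for a, b in zip(c, stop_triplet)) == 1
    ]
    return (near or codons)[0]


def enumerate_substitution_proteoforms(
    construct: CodingConstruct,
    site: StopCodonSite,
    candidates: Iterable[str] | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> list[Proteoform]:
    """One proteoform per candidate amino acid decoded at the stop site.

    ``candidates`` defaults to all 20 amino acids (an "all possible
    readthrough" database); pass the near-cognate set for a restricted
    database. Translation continues through the substituted residue to the
    construct's next in-frame stop codon.
    """
    aas = sorted(set(candidates)) if candidates is not None else list(ALL_AMINO_ACIDS)
    if not aas:
        raise InputError("candidate set is empty")
    unknown = [a for a in aas if a not in ALL_AMINO_ACIDS]
    if unknown:
        raise InputError(f"unknown amino acids in candidate set: {unknown}")
    out = []
    for aa in aas:
        codon = _pick_codon(aa, site.triplet, code)
        start = 3 * (site.codon_index - 1)
        cds = construct.cds[:start] + codon + construct.cds[start + 3 :]
        result = translate(cds, code)
        out.append(
            Proteoform(
                id=f"{construct.name}|{site.label}:sub:{aa}",
                sequence=result.protein,
                event="sub",
                site_label=site.label,
                incorporated=aa,
                cds=cds,
                ran_off_end=result.ran_off_end,
            )
        )
    return out


def enumerate_skip_proteoform(
    construct: CodingConstruct,
    site: StopCodonSite,
    code: GeneticCode = STANDARD_CODE,
) -> Proteoform:
    """The stop-skip proteoform: stop triplet deleted, frame preserved.

    Translation resumes immediately after the deleted triplet and terminates
    at the next in-frame stop; absence of a downstream stop is flagged as
    ``ran_off_end`` rather than raised.
    """
    start = 3 * (site.codon_index - 1)
    cds = construct.cds[:start] + construct.cds[start + 3 :]
    result = translate(cds, code)
    return Proteoform(
        id=f"{construct.name}|{site.label}:skip",
        sequence=result.protein,
        event="skip",
        site_label=site.label,
        cds=cds,
        ran_off_end=result.ran_off_end,
    )


def enumerate_frameshift_proteoforms(
    construct: CodingConstruct,
    site: StopCodonSite,
    shifts: Iterable[int] = DEFAULT_FRAMESHIFTS,
    code: GeneticCode = STANDARD_CODE,
) -> list[Proteoform]:
    """Frameshift proteoforms: resume k bases past the stop's 3' end.

    For shift k the product is the translation prefix before the stop plus
    the translation of the CDS from ``stop_end + k`` onward, in that shifted
    frame, to the next stop. Shifts whose resume point falls beyond the
    sequence are skipped with a warning; an immediate in-frame stop yields a
    zero-length extension, emitted but flagged.
    """
    out = []
    prefix_cds = construct.cds[: 3 * (site.codon_index - 1)]
    for k in sorted(set(shifts)):
        if k <= 0:
            raise InputError("frameshift must be positive")
        resume = 3 * site.codon_index + k
        if resume >= len(construct.cds):
            warnings.warn(
                f"{construct.name}:{site.label}: frameshift +{k} resumes beyond "
                "the sequence end; skipped"
            )
            continue
        cds = prefix_cds + construct.cds[resume:]
        result = translate(cds, code)
        extension = result.protein[len(prefix_cds) // 3 :]
        out.append(
            Proteoform(
                id=f"{construct.name}|{site.label}:fs:{k}",
                sequence=result.protein,
                event="fs",
                site_label=site.label,
                shift_k=k,
                cds=cds,
                ran_off_end=result.ran_off_end,
                zero_length_extension=(len(extension) == 0),
            )
        )
    return out


def _parse_header(header: str) -> dict:
    name, _, rest = header.partition("|")
    if not rest:
        raise ValidationError(f"malformed proteoform header {header!r}")
    parts = rest.split(":")
    if len(parts) < 2:
        raise ValidationError(f"malformed proteoform header {header!r}")
    site_label, event = parts[0], parts[1]
    incorporated = shift_k = None
    if event == "sub":
        incorporated = parts[2]
    elif event == "fs":
        shift_k = int(parts[2])
    elif event != "skip":
        raise ValidationError(f"unknown event {event!r} in header {header!r}")
    return dict(
        site_label=site_label, event=event, incorporated=incorporated, shift_k=shift_k
    )


def write_database(
    proteoforms: Sequence[Proteoform], path: str | Path
) -> Path:
    """Write a proteoform FASTA database (60-column wrapped).

    Header grammar: ``>name|<site-label>:<event>[:<aa or k>]``. Duplicate
    ids raise :class:`ValidationError`; round-trips losslessly through
    :func:`read_database`.
    """
    if not proteoforms:
        raise InputError("refusing to write an empty database")
    seen: set[str] = set()
    records = []
    for pf in proteoforms:
        if pf.id in seen:
            raise ValidationError(f"duplicate proteoform id {pf.id!r}")
        seen.add(pf.id)
        records.append(SeqRecord(Seq(pf.sequence), id=pf.id, description=""))
    path = Path(path)
    with path.open("w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(records)
    return path


def read_database(path: str | Path) -> list[Proteoform]:
    """Read a proteoform FASTA written by :func:`write_database`."""
    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        out.append(Proteoform(id=record.id, sequence=str(record.seq), **_parse_header(record.id)))
    return out
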