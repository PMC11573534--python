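"""In-silico proteolysis and peptide mass arithmetic.

Trypsin is modeled with the Keil rule: cleavage C-terminal to K or R, but not
when the next residue is proline (the exception is the common search-engine
default and is togglable). Full-tryptic peptides have both termini tryptic
(protein termini count); semi-tryptic peptides have exactly one tryptic
terminus and are bounded in length and mass to keep enumeration tractable.
Missed cleavages count internal K/R not followed by P.

Masses are monoisotopic throughout: a peptide's neutral mass is the sum of
its residue masses plus one water plus modification deltas, m/z at charge z
is (M + z*proton)/z, and CID b/y fragments obey the complementarity
b_i + y_(n-i) = M (neutral masses, modifications included).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .constants import (
    ACETYL_DELTA,
    CARBAMIDOMETHYL_DELTA,
    OXIDATION_DELTA,
    PROTON,
    RESIDUE_MASS,
    WATER,
)
from .errors import InputError
from .proteoforms import Proteoform, StopCodonSite

TRYPTIC_RESIDUES = frozenset("KR")


@dataclass(frozen=True)
class ModificationSpec:
    """A fixed or variable modification.

    ``targets`` is a string of residue letters, or the special value
    ``"protein-nterm"`` for protein N-terminal modifications (applied to
    peptides starting at position 1, or 2 to allow for initiator-Met
    clipping).
    """

    name: str
    targets: str
    delta_mass: float
    mode: str = "variable"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "variable"):
            raise InputError(f"modification mode must be fixed|variable, got {self.mode!r}")


CARBAMIDOMETHYL_C = ModificationSpec(
    "carbamidomethyl", "C", CARBAMIDOMETHYL_DELTA, "fixed"
)
OXIDATION_M = ModificationSpec("oxidation", "M", OXIDATION_DELTA, "variable")
ACETYL_PROTEIN_NTERM = ModificationSpec(
    "acetyl", "protein-nterm", ACETYL_DELTA, "variable"
)
DEFAULT_MODIFICATIONS = (CARBAMIDOMETHYL_C, OXIDATION_M, ACETYL_PROTEIN_NTERM)


@dataclass(frozen=True)
class Peptide:
    """A digestion product located on its parent proteoform(s).

    ``start``/``end`` are 1-based inclusive protein coordinates;
    ``cleavage_status`` is ``"full"``, ``"semi-N"`` (non-tryptic N-terminus)
    or ``"semi-C"`` (non-tryptic C-terminus). ``mods`` holds
    ``(position, spec)`` pairs where position is the 1-based residue within
    the peptide and 0 denotes the peptide N-terminus.
    """

    sequence: str
    start: int
    end: int
    missed_cleavages: int
    cleavage_status: str = "full"
    parent_ids: tuple[str, ...] = ()
    mods: tuple[tuple[int, ModificationSpec], ...] = ()

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise InputError("peptide coordinates inconsistent with sequence length")

    @property
    def mod_delta(self) -> float:
        return sum(spec.delta_mass for _, spec in self.mods)

    def mod_string(self) -> str:
        """Compact text form of the modification state, e.g. ``4:carbamidomethyl``."""
        return ";".join(f"{pos}:{spec.name}" for pos, spec in self.mods)


@dataclass(frozen=True)
class Fragment:
    """A b- or y-series CID fragment ion."""

    series: str
    index: int
    charge: int
    mz: float


def cleavage_bonds(sequence: str, exclude_proline: bool = True) -> list[int]:
    """Tryptic cleavage bonds: positions p where the bond after residue p cuts."""
    return [
        p
        for p in range(1, len(sequence))
        if sequence[p - 1] in TRYPTIC_RESIDUES
        and not (exclude_proline and sequence[p] == "P")
    ]


def peptide_mono_mass(peptide: "Peptide | str") -> float:
    """Neutral monoisotopic mass, modification deltas included."""
    if isinstance(peptide, Peptide):
        seq, delta = peptide.sequence, peptide.mod_delta
    else:
        seq, delta = peptide, 0.0
    if not seq:
        raise InputError("empty peptide sequence")
    try:
        mass = sum(RESIDUE_MASS[aa] for aa in seq)
    except KeyError as exc:
        raise InputError(f"unknown residue {exc.args[0]!r} in {seq!r}") from None
    return mass + WATER + delta


def precursor_mz(neutral_mass: float, z: int) -> float:
    """(M + z*proton)/z for a z+ precursor."""
    if z <= 0:
        raise InputError(f"charge must be >= 1, got {z}")
    return (neutral_mass + z * PROTON) / z


def digest(
    proteoform: "Proteoform | str",
    max_missed: int = 2,
    semi: bool = False,
    exclude_proline: bool = True,
    semi_min_length: int = 5,
    semi_max_length: int = 45,
    semi_max_mass: float = 6000.0,
) -> list[Peptide]:
    """Enumerate tryptic (and optionally semi-tryptic) peptides.

    Full-tryptic peptides with up to ``max_missed`` missed cleavages are
    always produced, without length bounds. With ``semi`` additionally every
    peptide with exactly one tryptic terminus within the stated length/mass
    bounds is produced. Output is deduplicated by (start, end) and sorted by
    coordinates; full-tryptic status wins over semi for identical spans.
    """
    if max_missed < 0:
        raise InputError("max_missed must be >= 0")
    if isinstance(proteoform, Proteoform):
        seq, parents = proteoform.sequence, (proteoform.id,)
    else:
        seq, parents = proteoform, ()
    n = len(seq)
    if n == 0:
        return []
    bonds = cleavage_bonds(seq, exclude_proline)
    boundaries = [0] + bonds + [n]
    found: dict[tuple[int, int], Peptide] = {}

    def emit(start: int, end: int, missed: int, status: str) -> None:
        key = (start, end)
        if key in found and (found[key].cleavage_status == "full" or status != "full"):
            return
        found[key] = Peptide(
            sequence=seq[start - 1 : end],
            start=start,
            end=end,
            missed_cleavages=missed,
            cleavage_status=status,
            parent_ids=parents,
        )

    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + max_missed + 2, len(boundaries))):
            emit(boundaries[i] + 1, boundaries[j], j - i - 1, "full")

    if semi:
        bond_set = set(bonds)

        def in_bounds(start: int, end: int) -> bool:
            length = end - start + 1
            return (
                semi_min_length <= length <= semi_max_length
                and peptide_mono_mass(seq[start - 1 : end]) <= semi_max_mass
            )

        tryptic_starts = [b + 1 for b in boundaries[:-1]]
        tryptic_ends = boundaries[1:]
        for s in tryptic_starts:
            missed = 0
            for e in range(s, min(n, s + semi_max_length - 1) + 1):
                if e > s and (e - 1) in bond_set:
                    missed += 1
                    if missed > max_missed:
                        break
                if e in bond_set or e == n:
                    continue  # tryptic C-terminus: covered by the full pass
                if in_bounds(s, e):
                    emit(s, e, missed, "semi-C")
        for e in tryptic_ends:
            missed = 0
            for s in range(e, max(1, e - semi_max_length + 1) - 1, -1):
                if s < e and s in bond_set:
                    missed += 1
                    if missed > max_missed:
                        break
                if (s - 1) in bond_set or s == 1:
                    continue  # tryptic N-terminus: covered by the full pass
                if in_bounds(s, e):
                    emit(s, e, missed, "semi-N")

    return [found[key] for key in sorted(found)]


def apply_modifications(
    peptide: Peptide,
    specs: Sequence[ModificationSpec] = DEFAULT_MODIFICATIONS,
    max_variable: int = 3,
) -> list[Peptide]:
    """Expand one peptide into its modified forms.

    Fixed modifications are applied to every matching residue of every form;
    variable modifications are expanded combinatorially over at most
    ``max_variable`` sites. Protein N-terminal modifications are considered
    for peptides with start <= 2 (allowing initiator-Met clipping).
    """
    if max_variable < 0:
        raise InputError("max_variable must be >= 0")
    fixed: list[tuple[int, ModificationSpec]] = []
    variable_sites: list[tuple[int, ModificationSpec]] = []
    for spec in specs:
        if spec.targets == "protein-nterm":
            if peptide.start <= 2:
                site = [(0, spec)]
            else:
                site = []
        else:
            site = [
                (pos, spec)
                for pos, aa in enumerate(peptide.sequence, start=1)
                if aa in spec.targets
            ]
        if spec.mode == "fixed":
            fixed.extend(site)
        else:
            variable_sites.extend(site)
    forms = []
    for r in range(0, min(max_variable, len(variable_sites)) + 1):
        for combo in itertools.combinations(variable_sites, r):
            positions = [p for p, _ in combo]
            if len(set(positions)) != len(positions):
                continue
            mods = tuple(sorted(fixed + list(combo), key=lambda m: (m[0], m[1].name)))
            forms.append(replace(peptide, mods=mods))
    return forms


def fragment_ions(peptide: Peptide, max_charge: int = 1) -> list[Fragment]:
    """All b/y fragments b_1..b_(n-1), y_1..y_(n-1) at charges 1..max_charge.

    Modifications contribute to the fragments containing their residue; a
    peptide N-terminal modification (position 0) travels with the b series.
    """
    seq = peptide.sequence
    n = len(seq)
    if n < 2:
        raise InputError("fragmentation needs a peptide of length >= 2")
    if max_charge < 1:
        raise InputError("max_charge must be >= 1")
    delta_at = [0.0] * (n + 1)
    for pos, spec in peptide.mods:
        delta_at[pos] += spec.delta_mass
    prefix = [0.0] * (n + 1)
    for i, aa in enumerate(seq, start=1):
        try:
            prefix[i] = prefix[i - 1] + RESIDUE_MASS[aa] + delta_at[i]
        except KeyError:
            raise InputError(f"unknown residue {aa!r} in {seq!r}") from None
    prefix_with_nterm = [p + delta_at[0] for p in prefix]
    total = prefix_with_nterm[n] + WATER
    out = []
    for i in range(1, n):
        b_neutral = prefix_with_nterm[i]
        y_neutral = total - b_neutral
        for z in range(1, max_charge + 1):
            out.append(Fragment("b", i, z, (b_neutral + z * PROTON) / z))
            out.append(Fragment("y", n - i, z, (y_neutral + z * PROTON) / z))
    return out


def site_residue_position(proteoform: Proteoform, site: StopCodonSite) -> int:
    """Protein coordinate diagnostic for an event at ``site``.

    Substitution proteoforms carry the incorporated residue at the site's
    codon index; skip and frameshift proteoforms lack that column, so the
    junction residue immediately upstream is used.
    """
    if proteoform.event == "sub":
        return site.codon_index
    return site.codon_index - 1


def diagnostic_peptides(
    proteoforms: Sequence[Proteoform],
    site: StopCodonSite,
    max_missed: int = 2,
    semi: bool = False,
    **digest_kwargs,
) -> dict[str, list[Peptide]]:
    """Per variant, the digestion peptides overlapping the site residue.

    Returns a map from variant key (incorporated residue, ``"skip"``,
    ``"fs<k>"``) to site-covering peptides. Variants with no recoverable
    peptide yield an empty list with a warning — mirroring sites where the
    nearest tryptic cleavage is too distant for the peptide to be observed.
    A warning is also emitted when variants produce different cleavage
    patterns (e.g. K/R incorporation creating a new cleavage site).
    """
    out: dict[str, list[Peptide]] = {}
    spans: set[tuple[tuple[int, int], ...]] = set()
    for pf in proteoforms:
        pos = site_residue_position(pf, site)
        peps = [
            p
            for p in digest(pf, max_missed=max_missed, semi=semi, **digest_kwargs)
            if p.start <= pos <= p.end
        ]
        out[pf.variant] = peps
        spans.add(tuple(sorted((p.start, p.end) for p in peps)))
        if not peps:
            warnings.warn(
                f"{pf.id}: no digestion peptide covers the site residue "
                f"(position {pos}); the variant is unrecoverable at these settings"
            )
    if len(spans) > 1:
        warnings.warn(
            f"site {site.label}: variants produce different cleavage patterns"
        )
    return out


def primary_diagnostic_peptide(
    peptides: Iterable[Peptide], min_length: int = 5, max_length: int = 45
) -> Peptide:
    """Deterministic choice of the best site-diagnostic peptide.

    Prefers peptides of searchable length (``min_length``..``max_length``,
    matching the search-space bounds), then full-tryptic status, then fewest
    missed cleavages, then shortest length, then lexicographic sequence.
    """
    peptides = list(peptides)
    if not peptides:
        raise InputError("no site-covering peptides to choose from")
    return min(
        peptides,
        key=lambda p: (
            not (min_length <= len(p.sequence) <= max_length),
            p.cleavage_status != "full",
            p.missed_cleavages,
            len(p.sequence),
            p.sequence,
        ),
    )


def peptide_table(
    peptides: Sequence[Peptide],
    specs: Sequence[ModificationSpec] = DEFAULT_MODIFICATIONS,
    max_variable: int = 3,
    charges: Sequence[int] = (1, 2),
) -> str:
    """Tab-separated peptide report with per-charge m/z columns."""
    header = ["sequence", "start", "end", "status", "missed", "mods", "mass"]
    header += [f"mz_z{z}" for z in charges]
    lines = ["\t".join(header)]
    for pep in peptides:
        for form in apply_modifications(pep, specs, max_variable):
            mass = peptide_mono_mass(form)
            row = [
                form.sequence,
                str(form.start),
                str(form.end),
                form.cleavage_status,
                str(form.missed_cleavages),
                form.mod_string() or "-",
                f"{mass:.5f}",
            ]
            row += [f"{precursor_mz(mass, z):.5f}" for z in charges]
            lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
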