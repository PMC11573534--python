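"""Peptide-spectrum matching with target-decoy FDR control.

The scorer is a deliberately simple shared-peak count weighted by relative
peak intensity — a transparent stand-in for commercial engine scores, which
this package does not attempt to reproduce. The quantities the pipeline is
built for (peptide masses, m/z, XIC areas, incorporation fractions) are
engine-independent.

Decoys: ``make_decoys`` defaults to whole-protein sequence reversal; the
``"pseudo"`` mode reverses each inter-cleavage segment while keeping the K/R
anchors in place, which preserves the tryptic peptide mass distribution of
the target database and is the pipeline default (see the methods note for
why that matters for FDR calibration).

q-values follow the standard target-decoy recipe: PSMs sorted by decreasing
score, running FDR estimate = #decoys / max(1, #targets), q = cumulative
minimum from the bottom of the list.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .constants import PROTON
from .digest import (
    DEFAULT_MODIFICATIONS,
    ModificationSpec,
    Peptide,
    apply_modifications,
    digest,
    fragment_ions,
    peptide_mono_mass,
    precursor_mz,
)
from .errors import InputError
from .io import Spectrum
from .proteoforms import Proteoform

DECOY_PREFIX = "DECOY_"


@dataclass(frozen=True)
class SearchConfig:
    """Search-engine style settings.

    Defaults mirror a typical Orbitrap CID workflow: 10 ppm precursor and
    0.6 Da fragment tolerance, full trypsin with up to two missed cleavages
    plus a semi-tryptic secondary search, fixed carbamidomethyl-C, variable
    Met oxidation and protein N-terminal acetylation, and a 1% peptide-level
    FDR threshold.
    """

    precursor_tol_ppm: float = 10.0
    fragment_tol_da: float = 0.6
    max_missed: int = 2
    semi: bool = True
    modifications: tuple[ModificationSpec, ...] = DEFAULT_MODIFICATIONS
    max_variable_mods: int = 3
    fdr_threshold: float = 0.01
    max_fragment_charge: int = 1
    decoy_mode: str = "pseudo"
    min_peptide_length: int = 5
    max_peptide_length: int = 45
    max_peptide_mass: float = 6000.0
    exclude_proline: bool = True

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_da <= 0:
            raise InputError("tolerances must be positive")
        if not 0 < self.fdr_threshold < 1:
            raise InputError("fdr_threshold must lie in (0, 1)")
        if self.decoy_mode not in ("reverse", "pseudo"):
            raise InputError("decoy_mode must be 'reverse' or 'pseudo'")


@dataclass
class PSM:
    """A peptide-spectrum match."""

    spectrum_id: str
    peptide: Peptide
    score: float
    matched_fragment_count: int
    is_decoy: bool
    precursor_mz: float
    charge: int
    retention_time: float
    q_value: float | None = None


def _pseudo_reverse(sequence: str, exclude_proline: bool = True) -> str:
    """Reverse each inter-cleavage segment, keeping K/R anchors in place."""
    from .digest import cleavage_bonds

    bonds = [0] + cleavage_bonds(sequence, exclude_proline) + [len(sequence)]
    parts = []
    for a, b in zip(bonds[:-1], bonds[1:]):
        segment = sequence[a:b]
        parts.append(segment[:-1][::-1] + segment[-1])
    return "".join(parts)


def make_decoys(
    proteoforms: Sequence[Proteoform],
    mode: str = "reverse",
    exclude_proline: bool = True,
) -> list[Proteoform]:
    """Decoy proteoforms, ids prefixed with ``DECOY_``, one per target.

    ``mode="reverse"`` reverses the whole sequence (K/R positions not
    preserved); ``mode="pseudo"`` reverses within cleavage segments so the
    decoy digest mass-matches the target digest. Decoys identical to their
    target (palindromes) are excluded with a warning.
    """
    if not proteoforms:
        raise InputError("no proteoforms to derive decoys from")
    out = []
    for pf in proteoforms:
        if mode == "reverse":
            seq = pf.sequence[::-1]
        else:
            seq = _pseudo_reverse(pf.sequence, exclude_proline)
        if seq == pf.sequence:
            warnings.warn(f"{pf.id}: decoy equals target (palindrome); excluded")
            continue
        out.append(replace(pf, id=DECOY_PREFIX + pf.id, sequence=seq, cds=None))
    return out


@dataclass(frozen=True)
class PeptideForm:
    """A unique (sequence, modification state) entry of the search space."""

    peptide: Peptide
    neutral_mass: float
    is_decoy: bool


class PeptideIndex:
    """Digested, modified peptide forms keyed by neutral mass.

    Decoy peptide forms whose sequence collides with a target sequence are
    dropped (the peptide-level analogue of palindromic decoy exclusion).
    """

    def __init__(
        self,
        targets: Sequence[Proteoform],
        decoys: Sequence[Proteoform] = (),
        config: SearchConfig | None = None,
    ) -> None:
        self.config = config or SearchConfig()
        cfg = self.config
        merged: dict[tuple[str, tuple, bool], Peptide] = {}
        for pf, is_decoy in [(p, False) for p in targets] + [(p, True) for p in decoys]:
            for pep in digest(
                pf,
                max_missed=cfg.max_missed,
                semi=cfg.semi,
                exclude_proline=cfg.exclude_proline,
                semi_min_length=cfg.min_peptide_length,
                semi_max_length=cfg.max_peptide_length,
                semi_max_mass=cfg.max_peptide_mass,
            ):
                if not cfg.min_peptide_length <= len(pep.sequence) <= cfg.max_peptide_length:
                    continue
                for form in apply_modifications(
                    pep, cfg.modifications, cfg.max_variable_mods
                ):
                    key = (
                        form.sequence,
                        tuple((p, s.name) for p, s in form.mods),
                        is_decoy,
                    )
                    if key in merged:
                        prev = merged[key]
                        merged[key] = replace(
                            prev,
                            parent_ids=tuple(
                                sorted(set(prev.parent_ids) | set(form.parent_ids))
                            ),
                        )
                    else:
                        merged[key] = form
        target_sequences = {seq for seq, _, dec in merged if not dec}
        self.n_shared_dropped = 0
        forms = []
        for (seq, _, is_decoy), pep in merged.items():
            if is_decoy and seq in target_sequences:
                self.n_shared_dropped += 1
                continue
            mass = peptide_mono_mass(pep)
            if mass > cfg.max_peptide_mass:
                continue
            forms.append(PeptideForm(pep, mass, is_decoy))
        forms.sort(key=lambda f: f.neutral_mass)
        self.forms = forms
        self._masses = [f.neutral_mass for f in forms]

    def __len__(self) -> int:
        return len(self.forms)

    def by_mass_window(self, lo: float, hi: float) -> list[PeptideForm]:
        i = bisect.bisect_left(self._masses, lo)
        j = bisect.bisect_right(self._masses, hi)
        return self.forms[i:j]


def candidate_filter(
    spectrum: Spectrum, index: PeptideIndex, config: SearchConfig | None = None
) -> list[PeptideForm]:
    """Peptide forms whose theoretical m/z at the spectrum charge lies within
    the precursor ppm tolerance (boundary inclusive)."""
    cfg = config or index.config
    if spectrum.charge < 1:
        raise InputError(f"spectrum {spectrum.id}: missing or invalid charge")
    tol = cfg.precursor_tol_ppm * 1e-6
    obs_neutral = (spectrum.precursor_mz - PROTON) * spectrum.charge
    margin = abs(obs_neutral) * tol * 2 + 1e-6
    out = []
    for form in index.by_mass_window(obs_neutral - margin, obs_neutral + margin):
        theo_mz = precursor_mz(form.neutral_mass, spectrum.charge)
        # boundary inclusive; the relative epsilon absorbs float rounding
        if abs(spectrum.precursor_mz - theo_mz) <= tol * theo_mz * (1 + 1e-9):
            out.append(form)
    return out


def score_psm(
    spectrum: Spectrum, form: PeptideForm, config: SearchConfig
) -> PSM:
    """Score a candidate: sum over matched b/y fragments of
    ``1 + log(1 + relative intensity)``.

    Peak-fragment pairs are assigned greedily by smallest m/z difference,
    each experimental peak matching at most one theoretical fragment and
    vice versa.
    """
    frags = fragment_ions(form.peptide, config.max_fragment_charge)
    score = 0.0
    matched = 0
    if len(spectrum):
        base = float(spectrum.intensity.max())
        pairs = []
        mz = spectrum.mz
        for fi, frag in enumerate(frags):
            lo = np.searchsorted(mz, frag.mz - config.fragment_tol_da, side="left")
            hi = np.searchsorted(mz, frag.mz + config.fragment_tol_da, side="right")
            for pi in range(lo, hi):
                pairs.append((abs(mz[pi] - frag.mz), pi, fi))
        pairs.sort()
        used_peaks: set[int] = set()
        used_frags: set[int] = set()
        for _, pi, fi in pairs:
            if pi in used_peaks or fi in used_frags:
                continue
            used_peaks.add(pi)
            used_frags.add(fi)
            rel = spectrum.intensity[pi] / base if base > 0 else 0.0
            score += 1.0 + float(np.log1p(rel))
            matched += 1
    return PSM(
        spectrum_id=spectrum.id,
        peptide=form.peptide,
        score=score,
        matched_fragment_count=matched,
        is_decoy=form.is_decoy,
        precursor_mz=spectrum.precursor_mz,
        charge=spectrum.charge,
        retention_time=spectrum.retention_time,
    )


def search_spectra(
    spectra: Sequence[Spectrum],
    index: PeptideIndex,
    config: SearchConfig | None = None,
) -> list[PSM]:
    """Best-scoring (rank-1) PSM per spectrum.

    Ties are broken by more matched fragments, then decoy before target
    (the conservative choice: an exact-score tie gives the decoy the win,
    so the FDR estimate cannot be deflated by tie ordering), then
    lexicographically smaller peptide sequence, for reproducibility.
    Spectra with no candidate in the precursor window yield no PSM.
    """
    cfg = config or index.config
    out = []
    for spectrum in spectra:
        candidates = candidate_filter(spectrum, index, cfg)
        if not candidates:
            continue
        psms = [score_psm(spectrum, form, cfg) for form in candidates]
        psms.sort(
            key=lambda p: (
                -p.score,
                -p.matched_fragment_count,
                not p.is_decoy,
                p.peptide.sequence,
            )
        )
        out.append(psms[0])
    return out


def assign_qvalues(
    psms: Sequence[PSM], decoys_searched: bool = False
) -> list[PSM]:
    """Attach target-decoy q-values; returns PSMs sorted by decreasing score.

    Requires decoy PSMs (or the caller's assertion via ``decoys_searched``
    that a decoy database was searched and simply produced no rank-1 PSM);
    without either, the FDR estimate is undefined and an error is raised.
    """
    psms = list(psms)
    if not psms:
        return []
    if not any(p.is_decoy for p in psms) and not decoys_searched:
        raise InputError(
            "no decoy PSMs present and no decoy database declared; "
            "q-values are undefined"
        )
    psms.sort(
        key=lambda p: (
            -p.score,
            -p.matched_fragment_count,
            not p.is_decoy,
            p.peptide.sequence,
        )
    )
    n_targets = 0
    n_decoys = 0
    fdrs = []
    for p in psms:
        if p.is_decoy:
            n_decoys += 1
        else:
            n_targets += 1
        fdrs.append(n_decoys / max(1, n_targets))
    q = float("inf")
    for i in range(len(psms) - 1, -1, -1):
        q = min(q, fdrs[i])
        psms[i].q_value = q
    return psms


def accepted_psms(psms: Iterable[PSM], threshold: float = 0.01) -> list[PSM]:
    """Accepted set: target PSMs with q-value at or below the threshold."""
    return [
        p
        for p in psms
        if not p.is_decoy and p.q_value is not None and p.q_value <= threshold
    ]


def psm_table(psms: Sequence[PSM]) -> str:
    """Tab-separated PSM report."""
    lines = [
        "spectrum_id\tsequence\tmods\tstart\tend\tscore\tmatched\t"
        "is_decoy\tq_value\tprecursor_mz\tcharge\trt_min"
    ]
    for p in psms:
        q = "" if p.q_value is None else f"{p.q_value:.6f}"
        lines.append(
            f"{p.spectrum_id}\t{p.peptide.sequence}\t{p.peptide.mod_string() or '-'}\t"
            f"{p.peptide.start}\t{p.peptide.end}\t{p.score:.4f}\t"
            f"{p.matched_fragment_count}\t{int(p.is_decoy)}\t{q}\t"
            f"{p.precursor_mz:.6f}\t{p.charge}\t{p.retention_time:.3f}"
        )
    return "\n".join(lines) + "\n"
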