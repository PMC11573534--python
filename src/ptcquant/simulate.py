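"""Ground-truth-annotated synthetic LC-MS/MS datasets.

The generator emulates the statistical structure the analysis relies on, at
desk scale: a mixture of site-variant peptides in stated proportions, each
eluting as a Gaussian chromatographic peak whose area is proportional to its
proportion; MS/MS spectra sampled near each apex containing singly-charged
b/y fragments with ppm-scale Gaussian mass error, Bernoulli peak dropout and
log-normal intensities; and uniform noise peaks. Everything is deterministic
under a fixed seed, and a ground-truth manifest records the true peptide of
every spectrum and the true area and fraction of every variant.

It does not emulate profile-mode peaks, isotope envelopes, chimeric spectra
or instrument drift.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .digest import (
    CARBAMIDOMETHYL_C,
    Peptide,
    apply_modifications,
    diagnostic_peptides,
    digest,
    fragment_ions,
    peptide_mono_mass,
    precursor_mz,
    primary_diagnostic_peptide,
)
from .errors import InputError
from .io import Chromatogram, Spectrum, write_chromatogram, write_mgf
from .proteoforms import Proteoform, StopCodonSite


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated run.

    The default mixture is the R/W/C proportions observed at an opal PTC in
    the readthrough model system; abundances are in arbitrary units matching
    the magnitude of reported ion intensities. ``mass_error_sd_ppm`` follows
    the sub-2-ppm precursor accuracy of a calibrated Orbitrap; the dropout
    and noise settings are declared desk-scale defaults, not instrument
    measurements.
    """

    mixture: Mapping[str, float] = field(
        default_factory=lambda: {"R": 0.545, "W": 0.308, "C": 0.147}
    )
    peptide_abundance_scale: float = 1.0e6
    elution_sd: float = 0.1  # minutes
    rt_span: float = 30.0  # minutes
    rt_grid_step: float = 0.01  # minutes
    min_apex_spacing: float = 2.0  # minutes
    mass_error_sd_ppm: float = 2.0
    fragment_dropout_prob: float = 0.1
    noise_peaks_per_spectrum: int = 10
    noise_intensity_range: tuple[float, float] = (50.0, 500.0)
    noise_mz_range: tuple[float, float] = (200.0, 1400.0)
    fragment_intensity_mu: float = 9.2  # log-scale, ~1e4 AU median
    fragment_intensity_sigma: float = 0.4
    spectra_per_variant: int = 3
    precursor_charge: int = 2
    include_flanking: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"mixture proportions sum to {total}, expected 1")
        if any(p < 0 for p in self.mixture.values()):
            raise InputError("mixture proportions must be non-negative")
        if not 0 <= self.fragment_dropout_prob < 1:
            raise InputError("fragment_dropout_prob must lie in [0, 1)")
        if self.elution_sd <= 0 or self.rt_span <= 0 or self.rt_grid_step <= 0:
            raise InputError("elution_sd, rt_span and rt_grid_step must be positive")
        if self.noise_peaks_per_spectrum < 0:
            raise InputError("noise_peaks_per_spectrum must be >= 0")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["mixture"] = dict(self.mixture)
        return json.dumps(d, sort_keys=True)


@dataclass
class GroundTruth:
    """What the generator actually put into the files."""

    site_label: str
    # spectrum id -> (channel, peptide sequence, mod string); channel is the
    # variant key, a variant's flanking channel, or "null".
    spectrum_truth: dict[str, tuple[str, str, str]]
    # variant -> (peptide sequence, mod string, true XIC area, true fraction)
    variant_truth: dict[str, tuple[str, str, float, float]]


@dataclass
class SimulatedDataset:
    spectra: list[Spectrum]
    chromatograms: list[Chromatogram]
    truth: GroundTruth
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write spectra.mgf, one chromatogram TSV per channel, and the
        ground-truth manifest; returns the paths keyed by artifact name."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["spectra"] = write_mgf(self.spectra, outdir / "spectra.mgf")
        for chrom in self.chromatograms:
            name = f"chrom_{chrom.label}.tsv"
            paths[name] = write_chromatogram(chrom, outdir / name)
        manifest = outdir / "ground_truth.tsv"
        with manifest.open("w") as handle:
            handle.write(f"# seed={self.config.seed}\n")
            handle.write(f"# config={self.config.to_json()}\n")
            handle.write("section\tname\tchannel\tpeptide\tmods\tvalue\n")
            for sid, (channel, seq, mods) in sorted(self.truth.spectrum_truth.items()):
                handle.write(f"spectrum\t{sid}\t{channel}\t{seq}\t{mods or '-'}\t\n")
            for variant, (seq, mods, area, frac) in sorted(
                self.truth.variant_truth.items()
            ):
                handle.write(
                    f"variant_area\t{variant}\t{variant}\t{seq}\t{mods or '-'}\t{area:.6g}\n"
                )
                handle.write(
                    f"variant_fraction\t{variant}\t{variant}\t{seq}\t{mods or '-'}\t{frac:.9f}\n"
                )
        paths["ground_truth"] = manifest
        return paths


def _fixed_form(peptide: Peptide) -> Peptide:
    """The peptide with fixed carbamidomethyl-C applied and no variable mods."""
    return apply_modifications(peptide, (CARBAMIDOMETHYL_C,), max_variable=0)[0]


def _place_apexes(
    rng: np.random.Generator, n: int, config: SimulationConfig
) -> np.ndarray:
    """Uniform apexes over the RT span with minimum spacing enforced by
    redrawing the whole set (so XIC windows never overlap)."""
    margin = 3 * config.elution_sd + 1.0
    lo, hi = margin, config.rt_span - margin
    if hi <= lo or (n > 1 and (hi - lo) < (n - 1) * config.min_apex_spacing):
        raise InputError("rt_span too short for the requested apex spacing")
    for _ in range(1000):
        apexes = np.sort(rng.uniform(lo, hi, size=n))
        if n == 1 or np.min(np.diff(apexes)) >= config.min_apex_spacing:
            return apexes
    raise InputError("could not place elution apexes with the requested spacing")


def _simulate_spectrum(
    rng: np.random.Generator,
    form: Peptide,
    spectrum_id: str,
    rt: float,
    config: SimulationConfig,
) -> Spectrum:
    theo_mz = precursor_mz(peptide_mono_mass(form), config.precursor_charge)
    obs_mz = theo_mz * (1.0 + rng.normal(0.0, config.mass_error_sd_ppm) * 1e-6)
    mzs: list[float] = []
    intens: list[float] = []
    for frag in fragment_ions(form, max_charge=1):
        if rng.random() < config.fragment_dropout_prob:
            continue
        mzs.append(frag.mz * (1.0 + rng.normal(0.0, config.mass_error_sd_ppm) * 1e-6))
        intens.append(
            float(
                rng.lognormal(config.fragment_intensity_mu, config.fragment_intensity_sigma)
            )
        )
    for _ in range(config.noise_peaks_per_spectrum):
        mzs.append(float(rng.uniform(*config.noise_mz_range)))
        intens.append(float(rng.uniform(*config.noise_intensity_range)))
    return Spectrum(
        id=spectrum_id,
        precursor_mz=obs_mz,
        charge=config.precursor_charge,
        retention_time=rt,
        mz=np.array(mzs),
        intensity=np.array(intens),
    )


def _flanking_peptide(proteoform: Proteoform, diagnostic: Peptide) -> Peptide | None:
    """The zero-missed full-tryptic peptide immediately C-terminal to the
    diagnostic peptide, if one of searchable length exists."""
    for pep in digest(proteoform, max_missed=0, semi=False):
        if pep.start == diagnostic.end + 1 and 5 <= len(pep.sequence) <= 45:
            return pep
    return None


def simulate_dataset(
    proteoforms: Sequence[Proteoform],
    site: StopCodonSite,
    config: SimulationConfig | None = None,
) -> SimulatedDataset:
    """Simulate spectra + chromatograms for a site-variant mixture.

    Every mixture key must name a variant among ``proteoforms`` (the
    incorporated residue for substitution proteoforms, ``"skip"``/``"fs<k>"``
    otherwise). Each variant contributes a Gaussian elution trace with area
    ``proportion * peptide_abundance_scale`` and ``spectra_per_variant``
    MS/MS spectra of its primary site-diagnostic peptide near the apex. With
    ``include_flanking`` the zero-missed tryptic neighbour immediately
    C-terminal to each diagnostic peptide is simulated as well (same
    proportion, own trace), emulating the cleavage products of a restored
    K/R site.
    """
    config = config or SimulationConfig()
    if not proteoforms:
        raise InputError("no proteoforms supplied")
    by_variant = {pf.variant: pf for pf in proteoforms}
    unknown = sorted(set(config.mixture) - set(by_variant))
    if unknown:
        raise InputError(f"mixture references unknown variants: {unknown}")
    diag = diagnostic_peptides(
        [by_variant[v] for v in sorted(config.mixture)], site
    )
    # channel = (key, peptide form, proportion); deterministic order
    channels: list[tuple[str, Peptide, float]] = []
    for variant in sorted(config.mixture):
        pep = _fixed_form(primary_diagnostic_peptide(diag[variant]))
        channels.append((variant, pep, config.mixture[variant]))
        if config.include_flanking:
            flank = _flanking_peptide(by_variant[variant], pep)
            if flank is not None:
                channels.append((f"{variant}_flank", _fixed_form(flank), config.mixture[variant]))

    rng = np.random.default_rng(config.seed)
    apexes = _place_apexes(rng, len(channels), config)
    grid = np.arange(0.0, config.rt_span + config.rt_grid_step / 2, config.rt_grid_step)
    spectra: list[Spectrum] = []
    chromatograms: list[Chromatogram] = []
    spectrum_truth: dict[str, tuple[str, str, str]] = {}
    variant_truth: dict[str, tuple[str, str, float, float]] = {}
    for (key, form, proportion), apex in zip(channels, apexes):
        mass = peptide_mono_mass(form)
        target_mz = precursor_mz(mass, config.precursor_charge)
        area = proportion * config.peptide_abundance_scale
        amp = area / (config.elution_sd * math.sqrt(2.0 * math.pi))
        trace = amp * np.exp(-0.5 * ((grid - apex) / config.elution_sd) ** 2)
        chromatograms.append(
            Chromatogram(target_mz=target_mz, rt=grid, intensity=trace, label=key)
        )
        for q in range(config.spectra_per_variant):
            rt = float(apex + rng.normal(0.0, 0.2 * config.elution_sd))
            sid = f"sim|{site.label}|{key}|{q:02d}"
            spectra.append(_simulate_spectrum(rng, form, sid, rt, config))
            spectrum_truth[sid] = (key, form.sequence, form.mod_string())
        if key in config.mixture:
            variant_truth[key] = (form.sequence, form.mod_string(), area, proportion)
    truth = GroundTruth(
        site_label=site.label,
        spectrum_truth=spectrum_truth,
        variant_truth=variant_truth,
    )
    return SimulatedDataset(spectra, chromatograms, truth, config)


def _shuffle_absent(
    rng: np.random.Generator, sequence: str, forbidden: set[str]
) -> str:
    for _ in range(200):
        shuffled = "".join(rng.permutation(list(sequence)))
        if shuffled not in forbidden:
            return shuffled
    raise InputError(f"could not shuffle {sequence!r} into an absent sequence")


def simulate_null_dataset(
    proteoforms: Sequence[Proteoform],
    site: StopCodonSite,
    config: SimulationConfig | None = None,
    n_spectra: int | None = None,
    forbidden_sequences: set[str] | None = None,
    source_peptides: Sequence[Peptide] | None = None,
) -> SimulatedDataset:
    """Spectra of shuffled peptides absent from the target database.

    Used to verify the target-decoy FDR estimator: a search of these spectra
    must not accept target PSMs beyond the stated FDR. Each null spectrum is
    generated from a residue permutation of a source peptide (same
    composition, hence a mass-matched but sequence-wrong foreign peptide).
    Sources are drawn at random from ``source_peptides`` when given — a
    diverse pool averages out sequence-specific match biases — otherwise the
    site's diagnostic peptides are used round-robin. Pass the searched
    target sequences as ``forbidden_sequences`` to guarantee absence from
    the database. No chromatograms are produced.
    """
    config = config or SimulationConfig()
    if not proteoforms:
        raise InputError("no proteoforms supplied")
    by_variant = {pf.variant: pf for pf in proteoforms}
    unknown = sorted(set(config.mixture) - set(by_variant))
    if unknown:
        raise InputError(f"mixture references unknown variants: {unknown}")
    diag = diagnostic_peptides([by_variant[v] for v in sorted(config.mixture)], site)
    diag_forms = [
        primary_diagnostic_peptide(diag[v]) for v in sorted(config.mixture)
    ]
    pool = list(source_peptides) if source_peptides else diag_forms
    if not pool:
        raise InputError("no source peptides for null spectra")
    forbidden = set(forbidden_sequences or set()) | {p.sequence for p in diag_forms}
    rng = np.random.default_rng(config.seed)
    total = n_spectra if n_spectra is not None else config.spectra_per_variant * len(diag_forms)
    spectra: list[Spectrum] = []
    spectrum_truth: dict[str, tuple[str, str, str]] = {}
    for q in range(total):
        if source_peptides:
            source = pool[int(rng.integers(len(pool)))]
        else:
            source = pool[q % len(pool)]
        shuffled_seq = _shuffle_absent(rng, source.sequence, forbidden)
        shuffled = Peptide(
            sequence=shuffled_seq,
            start=1,
            end=len(shuffled_seq),
            missed_cleavages=0,
            cleavage_status="full",
        )
        form = _fixed_form(shuffled)
        rt = float(rng.uniform(1.0, config.rt_span - 1.0))
        sid = f"null|{site.label}|{q:03d}"
        spectra.append(_simulate_spectrum(rng, form, sid, rt, config))
        spectrum_truth[sid] = ("null", form.sequence, form.mod_string())
    truth = GroundTruth(site.label, spectrum_truth, variant_truth={})
    return SimulatedDataset(spectra, [], truth, config)
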