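"""Model/Results facade over the search + quantification stages.

:class:`ReadthroughQuant` is constructed from data (spectra, chromatograms)
and a proteoform search database; :meth:`ReadthroughQuant.fit` runs the
target-decoy search, accepts peptide-spectrum matches at the configured FDR,
integrates the extracted ion chromatogram of every identified site variant
and returns a :class:`ReadthroughResults` carrying the per-site
incorporation-fraction estimates, their delta-method standard errors (from
chromatogram baseline noise), search diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .digest import diagnostic_peptides, peptide_mono_mass, precursor_mz
from .errors import InputError
from .io import Chromatogram, Spectrum, read_chromatograms, read_mgf
from .proteoforms import Proteoform, StopCodonSite, read_database
from .quant import (
    SiteQuantRecord,
    fraction_standard_errors,
    incorporation_fractions,
    xic_area,
    xic_noise_sd,
)
from .search import (
    PSM,
    PeptideIndex,
    SearchConfig,
    accepted_psms,
    assign_qvalues,
    make_decoys,
    search_spectra,
)


class ReadthroughQuant:
    """Per-site incorporation quantification model.

    Parameters
    ----------
    spectra : centroided MS/MS spectra to search.
    chromatograms : precursor XIC traces for the site-variant peptides.
    proteoforms : the target readthrough proteoform database.
    sites : the stop-codon sites to quantify.
    config : search settings; defaults to :class:`SearchConfig`.
    rt_window : half-width (minutes) of the XIC integration window.
    index : optionally a prebuilt :class:`PeptideIndex` (targets + decoys),
        so repeated fits against the same database skip digestion.
    """

    def __init__(
        self,
        spectra: Sequence[Spectrum],
        chromatograms: Sequence[Chromatogram],
        proteoforms: Sequence[Proteoform],
        sites: Sequence[StopCodonSite],
        config: SearchConfig | None = None,
        rt_window: float = 0.5,
        index: PeptideIndex | None = None,
    ) -> None:
        if not proteoforms:
            raise InputError("empty proteoform database")
        if not sites:
            raise InputError("no stop-codon sites to quantify")
        self.spectra = list(spectra)
        self.chromatograms = list(chromatograms)
        self.proteoforms = list(proteoforms)
        self.sites = list(sites)
        self.config = config or SearchConfig()
        self.rt_window = rt_window
        self._index = index

    @classmethod
    def from_files(
        cls,
        mgf_path: str | Path,
        chromatogram_paths: Iterable[str | Path],
        database_path: str | Path,
        sites: Sequence[StopCodonSite],
        config: SearchConfig | None = None,
        rt_window: float = 0.5,
    ) -> "ReadthroughQuant":
        return cls(
            spectra=read_mgf(mgf_path),
            chromatograms=read_chromatograms(chromatogram_paths),
            proteoforms=read_database(database_path),
            sites=sites,
            config=config,
            rt_window=rt_window,
        )

    @property
    def index(self) -> PeptideIndex:
        if self._index is None:
            decoys = make_decoys(self.proteoforms, mode=self.config.decoy_mode)
            self._index = PeptideIndex(self.proteoforms, decoys, self.config)
        return self._index

    def _chromatogram_for(self, theo_mz: float) -> Chromatogram | None:
        tol = self.config.precursor_tol_ppm * 1e-6
        best = None
        best_delta = np.inf
        for chrom in self.chromatograms:
            delta = abs(chrom.target_mz - theo_mz)
            if delta <= tol * theo_mz and delta < best_delta:
                best, best_delta = chrom, delta
        return best

    def _quantify_site(
        self, site: StopCodonSite, accepted: Sequence[PSM]
    ) -> SiteQuantRecord:
        site_pfs = [pf for pf in self.proteoforms if pf.site_label == site.label]
        if not site_pfs:
            raise InputError(f"no proteoforms in the database for site {site.label}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            diag = diagnostic_peptides(
                site_pfs,
                site,
                max_missed=self.config.max_missed,
                semi=False,
                exclude_proline=self.config.exclude_proline,
            )
        seq_to_variants: dict[str, set[str]] = {}
        for variant, peps in diag.items():
            for pep in peps:
                seq_to_variants.setdefault(pep.sequence, set()).add(variant)
        areas: dict[str, float] = {}
        ses: dict[str, float] = {}
        peptides: dict[str, str] = {}
        best_by_variant: dict[str, PSM] = {}
        for psm in accepted:
            variants = seq_to_variants.get(psm.peptide.sequence)
            if not variants:
                continue
            if len(variants) > 1:
                warnings.warn(
                    f"peptide {psm.peptide.sequence} is ambiguous between variants "
                    f"{sorted(variants)}; skipped for quantification"
                )
                continue
            (variant,) = variants
            prev = best_by_variant.get(variant)
            if prev is None or psm.score > prev.score:
                best_by_variant[variant] = psm
        for variant, psm in sorted(best_by_variant.items()):
            theo_mz = precursor_mz(peptide_mono_mass(psm.peptide), psm.charge)
            chrom = self._chromatogram_for(theo_mz)
            if chrom is None:
                warnings.warn(
                    f"{site.label}:{variant}: no chromatogram within "
                    f"{self.config.precursor_tol_ppm} ppm of m/z {theo_mz:.4f}"
                )
                continue
            area = xic_area(chrom, psm.retention_time, self.rt_window)
            noise = xic_noise_sd(chrom, psm.retention_time, self.rt_window)
            mask = (chrom.rt >= psm.retention_time - self.rt_window) & (
                chrom.rt <= psm.retention_time + self.rt_window
            )
            n = int(mask.sum())
            step = float(np.median(np.diff(chrom.rt[mask]))) if n > 1 else 0.0
            areas[variant] = area
            ses[variant] = noise * step * np.sqrt(max(n, 1))
            peptides[variant] = psm.peptide.sequence
        if not areas:
            warnings.warn(f"site {site.label}: no variant identified; empty record")
            return SiteQuantRecord(site_label=site.label, variants=(), all_zero=True)
        return incorporation_fractions(site.label, areas, peptides, ses)

    def fit(self) -> "ReadthroughResults":
        """Search, control FDR, integrate XICs and estimate fractions."""
        psms = search_spectra(self.spectra, self.index, self.config)
        psms = assign_qvalues(psms, decoys_searched=True)
        accepted = accepted_psms(psms, self.config.fdr_threshold)
        records = [self._quantify_site(site, accepted) for site in self.sites]
        return ReadthroughResults(
            model=self, psms=psms, accepted=accepted, site_records=records
        )


@dataclass
class ReadthroughResults:
    """Fit output: estimates, uncertainties, diagnostics, summary table."""

    model: ReadthroughQuant
    psms: list[PSM]
    accepted: list[PSM]
    site_records: list[SiteQuantRecord]
    params: pd.Series = field(init=False)
    bse: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        idx: list[tuple[str, str]] = []
        values: list[float] = []
        errors: list[float] = []
        for record in self.site_records:
            ses = fraction_standard_errors(record)
            for v in record.variants:
                idx.append((record.site_label, v.variant))
                values.append(np.nan if v.fraction is None else v.fraction)
                errors.append(ses[v.variant])
        multi = pd.MultiIndex.from_tuples(idx, names=["site", "variant"]) if idx else None
        self.params = pd.Series(values, index=multi, name="fraction", dtype=float)
        self.bse = pd.Series(errors, index=multi, name="se", dtype=float)

    @property
    def n_spectra(self) -> int:
        return len(self.model.spectra)

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)

    @property
    def n_decoy_psms(self) -> int:
        return sum(p.is_decoy for p in self.psms)

    def psm_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spectrum_id": [p.spectrum_id for p in self.psms],
                "sequence": [p.peptide.sequence for p in self.psms],
                "mods": [p.peptide.mod_string() for p in self.psms],
                "score": [p.score for p in self.psms],
                "matched": [p.matched_fragment_count for p in self.psms],
                "is_decoy": [p.is_decoy for p in self.psms],
                "q_value": [p.q_value for p in self.psms],
                "rt_min": [p.retention_time for p in self.psms],
            }
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for record in self.site_records:
            ses = fraction_standard_errors(record)
            for v in record.variants:
                rows.append(
                    {
                        "site": record.site_label,
                        "variant": v.variant,
                        "peptide": v.peptide,
                        "area": v.area,
                        "fraction": v.fraction,
                        "se": ses[v.variant],
                        "percent": None if v.fraction is None else round(100 * v.fraction, 1),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        cfg = self.model.config
        width = 72
        lines = [
            "Readthrough incorporation quantification".center(width),
            "=" * width,
            f"spectra searched: {self.n_spectra:<6d} PSMs: {len(self.psms):<6d} "
            f"accepted (q <= {cfg.fdr_threshold:g}): {self.n_accepted}",
            f"database forms: {len(self.model.index):<8d} decoy PSMs: {self.n_decoy_psms}",
            "-" * width,
            f"{'site':<10}{'variant':<9}{'peptide':<22}{'area':>11}{'fraction':>9}{'se':>8}",
        ]
        for record in self.site_records:
            ses = fraction_standard_errors(record)
            if not record.variants:
                lines.append(f"{record.site_label:<10}(no variants identified)")
                continue
            for v in record.variants:
                frac = "nan" if v.fraction is None else f"{v.fraction:.3f}"
                lines.append(
                    f"{record.site_label:<10}{v.variant:<9}{v.peptide:<22}"
                    f"{v.area:>11.4g}{frac:>9}{ses[v.variant]:>8.3f}"
                )
        lines.append("=" * width)
        return "\n".join(lines)
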