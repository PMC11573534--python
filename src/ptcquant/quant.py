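"""XIC-area quantification of per-site incorporation fractions.

Peptide abundance is proxied by the area under its extracted ion
chromatogram (XIC) peak: a trapezoidal integral over a fixed retention-time
window around the identified apex, after subtracting a baseline estimated as
the median intensity at the window edges. Per-site incorporation fractions
are the variant areas normalized to their sum — label-free, within-sample
only; no cross-sample normalization is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import InputError
from .io import Chromatogram


def xic_area(
    chromatogram: Chromatogram,
    rt_center: float,
    rt_window: float = 0.5,
    edge_points: int = 3,
) -> float:
    """Baseline-subtracted trapezoidal XIC area over ``rt_center +- rt_window``.

    The baseline is the median of the first and last ``edge_points`` grid
    intensities inside the window; the subtracted trace is floored at zero
    before integration, so the area is always non-negative. An empty window
    returns 0 with a warning.
    """
    if rt_window <= 0:
        raise InputError("rt_window must be positive")
    mask = (chromatogram.rt >= rt_center - rt_window) & (
        chromatogram.rt <= rt_center + rt_window
    )
    if mask.sum() < 2:
        warnings.warn(
            f"XIC window {rt_center:.2f}+-{rt_window:.2f} min contains "
            f"{int(mask.sum())} grid points; area set to 0"
        )
        return 0.0
    rt = chromatogram.rt[mask]
    inten = chromatogram.intensity[mask]
    k = min(edge_points, len(inten))
    baseline = float(np.median(np.concatenate([inten[:k], inten[-k:]])))
    corrected = np.clip(inten - baseline, 0.0, None)
    return float(np.trapezoid(corrected, rt))


def xic_noise_sd(
    chromatogram: Chromatogram,
    rt_center: float,
    rt_window: float = 0.5,
    edge_points: int = 3,
) -> float:
    """Point-noise estimate: standard deviation of the window-edge residuals.

    Used to propagate an area uncertainty (independent-noise approximation);
    zero for noise-free traces.
    """
    mask = (chromatogram.rt >= rt_center - rt_window) & (
        chromatogram.rt <= rt_center + rt_window
    )
    if mask.sum() < 2:
        return 0.0
    inten = chromatogram.intensity[mask]
    k = min(edge_points, len(inten))
    edges = np.concatenate([inten[:k], inten[-k:]])
    return float(np.std(edges - np.median(edges)))


@dataclass(frozen=True)
class VariantQuant:
    """Quantification of one variant at one site."""

    variant: str
    peptide: str
    area: float
    fraction: float | None
    area_se: float = 0.0


@dataclass(frozen=True)
class SiteQuantRecord:
    """Per-site map from incorporated variant to XIC area and fraction.

    ``fractions`` are areas normalized to their sum; when every area is zero
    the fractions are undefined (``None``) and ``all_zero`` is set.
    """

    site_label: str
    variants: tuple[VariantQuant, ...]
    all_zero: bool = field(default=False)

    def fraction(self, variant: str) -> float | None:
        for v in self.variants:
            if v.variant == variant:
                return v.fraction
        raise InputError(f"{self.site_label}: no variant {variant!r}")

    def percent(self, variant: str) -> float | None:
        """Fraction as a percentage rounded to one decimal place."""
        f = self.fraction(variant)
        return None if f is None else round(100.0 * f, 1)

    def areas(self) -> dict[str, float]:
        return {v.variant: v.area for v in self.variants}


def incorporation_fractions(
    site_label: str,
    variant_areas: Mapping[str, float],
    peptides: Mapping[str, str] | None = None,
    area_ses: Mapping[str, float] | None = None,
) -> SiteQuantRecord:
    """Normalize per-variant XIC areas into incorporation fractions.

    ``fraction_v = area_v / sum(areas)``; zero-area variants get fraction 0
    and removing them leaves the other fractions unchanged. All areas zero
    is flagged (fractions undefined) with a warning rather than an error.
    """
    if not variant_areas:
        raise InputError("no variant areas supplied")
    for variant, area in variant_areas.items():
        if area < 0:
            raise InputError(f"negative area for variant {variant!r}")
    total = float(sum(variant_areas.values()))
    all_zero = total == 0.0
    if all_zero:
        warnings.warn(f"site {site_label}: all variant areas are zero; fractions undefined")
    peptides = peptides or {}
    area_ses = area_ses or {}
    variants = tuple(
        VariantQuant(
            variant=v,
            peptide=peptides.get(v, ""),
            area=float(a),
            fraction=None if all_zero else float(a) / total,
            area_se=float(area_ses.get(v, 0.0)),
        )
        for v, a in sorted(variant_areas.items())
    )
    return SiteQuantRecord(site_label=site_label, variants=variants, all_zero=all_zero)


def fraction_standard_errors(record: SiteQuantRecord) -> dict[str, float]:
    """Delta-method standard errors of the fractions from the area SEs.

    With p_i = a_i / S, Var(p_i) = sum_j (dp_i/da_j)^2 Var(a_j) assuming
    independent area errors; zero when no area uncertainty is available.
    """
    areas = np.array([v.area for v in record.variants])
    ses = np.array([v.area_se for v in record.variants])
    total = areas.sum()
    out: dict[str, float] = {}
    for i, v in enumerate(record.variants):
        if record.all_zero:
            out[v.variant] = float("nan")
            continue
        grads = -areas[i] / total**2 * np.ones_like(areas)
        grads[i] = (total - areas[i]) / total**2
        out[v.variant] = float(np.sqrt(np.sum((grads * ses) ** 2)))
    return out


def quant_table(records: list[SiteQuantRecord]) -> str:
    """Tab-separated per-site quantification report."""
    lines = ["site\tvariant\tpeptide\tarea\tfraction\tpercent"]
    for record in records:
        for v in record.variants:
            frac = "" if v.fraction is None else f"{v.fraction:.6f}"
            pct = "" if v.fraction is None else f"{100 * v.fraction:.1f}"
            lines.append(
                f"{record.site_label}\t{v.variant}\t{v.peptide}\t"
                f"{v.area:.6g}\t{frac}\t{pct}"
            )
    return "\n".join(lines) + "\n"
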