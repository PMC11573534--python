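"""Peak-list and chromatogram containers and their on-disk formats.

Spectra travel as centroided MGF (``BEGIN IONS``/``END IONS`` blocks with
TITLE, PEPMASS, CHARGE and RTINSECONDS), read and written through pyteomics.
Chromatograms are tab-separated ``rt_min``/``intensity`` traces with ``#``
key=value metadata lines carrying the target m/z.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf

from .errors import InputError


@dataclass
class Spectrum:
    """One centroided MS/MS spectrum with its precursor information."""

    id: str
    precursor_mz: float
    charge: int
    retention_time: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise InputError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise InputError("negative peak intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class Chromatogram:
    """An RT-indexed intensity trace at a fixed target m/z."""

    target_mz: float
    rt: np.ndarray  # minutes, strictly increasing
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise InputError("rt and intensity grids differ in length")
        if len(self.rt) and np.any(np.diff(self.rt) <= 0):
            raise InputError("rt grid must be strictly increasing")
        if np.any(self.intensity < 0):
            raise InputError("negative chromatogram intensity")


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> Path:
    """Write spectra as MGF; peak lists are formatted at fixed precision so
    identical inputs produce byte-identical files."""
    path = Path(path)
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": {
                    "title": s.id,
                    "pepmass": round(s.precursor_mz, 6),
                    "charge": s.charge,
                    "rtinseconds": round(s.retention_time * 60.0, 3),
                },
            }
        )
    with path.open("w") as handle:
        mgf.write(
            entries,
            handle,
            fragment_format="{:.6f} {:.3f}",
            use_numpy=False,
            write_charges=False,
        )
    return path


def read_mgf(path: str | Path) -> list[Spectrum]:
    out = []
    with mgf.read(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge_field = params.get("charge")
            charge = int(charge_field[0]) if charge_field else 0
            rt_s = float(params.get("rtinseconds", 0.0))
            out.append(
                Spectrum(
                    id=str(params.get("title", "")),
                    precursor_mz=float(params["pepmass"][0]),
                    charge=charge,
                    retention_time=rt_s / 60.0,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                )
            )
    return out


def write_chromatogram(chrom: Chromatogram, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as handle:
        handle.write(f"# target_mz={chrom.target_mz:.6f}\n")
        if chrom.label:
            handle.write(f"# label={chrom.label}\n")
        handle.write("rt_min\tintensity\n")
        for rt, inten in zip(chrom.rt, chrom.intensity):
            handle.write(f"{rt:.4f}\t{inten:.4f}\n")
    return path


def read_chromatogram(path: str | Path) -> Chromatogram:
    meta: dict[str, str] = {}
    rts: list[float] = []
    intens: list[float] = []
    with Path(path).open() as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
                continue
            if line.startswith("rt_min"):
                continue
            rt_txt, inten_txt = line.split("\t")
            rts.append(float(rt_txt))
            intens.append(float(inten_txt))
    if "target_mz" not in meta:
        raise InputError(f"{path}: missing '# target_mz=' metadata line")
    return Chromatogram(
        target_mz=float(meta["target_mz"]),
        rt=np.array(rts),
        intensity=np.array(intens),
        label=meta.get("label", ""),
    )


def read_chromatograms(paths: Iterable[str | Path]) -> list[Chromatogram]:
    return [read_chromatogram(p) for p in paths]
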