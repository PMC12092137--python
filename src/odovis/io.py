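"""CSV dialects shared by the CLI and pipeline.

All tabular outputs are plain CSV with optional metadata lines prefixed
``#`` before the header; readers skip them.  Spectra are two-column
``wavelength_nm,<value>`` files plus a manifest CSV mapping files to
labels and replicate ids.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import AbsorbanceSpectrum
from .visual_models import SpectrumFunction

__all__ = [
    "write_csv",
    "read_csv",
    "write_spectrum",
    "read_spectrum",
    "read_spectrum_function",
    "write_spectra_dir",
    "read_spectra_manifest",
]


def write_csv(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_spectrum(spec: AbsorbanceSpectrum | SpectrumFunction, path: str | Path,
                   value_col: str = "absorbance") -> Path:
    values = spec.absorbance if hasattr(spec, "absorbance") else spec.value
    df = pd.DataFrame({"wavelength_nm": spec.wavelength_nm, value_col: values})
    return write_csv(df, path)


def read_spectrum(path: str | Path, label: str = "", replicate_id: int | None = None
                  ) -> AbsorbanceSpectrum:
    df = read_csv(path)
    wl = df.iloc[:, 0].to_numpy(float)
    ab = df.iloc[:, 1].to_numpy(float)
    return AbsorbanceSpectrum(wl, ab, label=label or Path(path).stem, replicate_id=replicate_id)


def read_spectrum_function(path: str | Path, role: str = "reflectance") -> SpectrumFunction:
    df = read_csv(path)
    return SpectrumFunction(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float), role)


def write_spectra_dir(spectra: list[AbsorbanceSpectrum], out_dir: str | Path) -> Path:
    """Write one two-column CSV per spectrum plus a manifest.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for spec in spectra:
        rep = spec.replicate_id if spec.replicate_id is not None else 0
        name = f"{spec.label}_r{rep}.csv"
        write_spectrum(spec, out_dir / name)
        rows.append({"file": name, "label": spec.label, "replicate_id": rep})
    manifest = out_dir / "manifest.csv"
    write_csv(pd.DataFrame(rows), manifest)
    return manifest


def read_spectra_manifest(manifest_path: str | Path) -> list[AbsorbanceSpectrum]:
    manifest_path = Path(manifest_path)
    df = read_csv(manifest_path)
    out = []
    for _, row in df.iterrows():
        out.append(
            read_spectrum(manifest_path.parent / row["file"], label=row["label"],
                          replicate_id=int(row["replicate_id"]))
        )
    return out


def mean_spectrum(replicates: list[AbsorbanceSpectrum]) -> AbsorbanceSpectrum:
    """Pointwise mean of replicate spectra sharing one wavelength grid."""
    wl = replicates[0].wavelength_nm
    for r in replicates[1:]:
        if not np.array_equal(r.wavelength_nm, wl):
            raise ValueError("replicates must share a wavelength grid")
    mean = np.mean([r.absorbance for r in replicates], axis=0)
    return AbsorbanceSpectrum(wl, mean, label=replicates[0].label)
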