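"""Shared in-memory containers for spectra and feature tables.

The package passes two containers between stages: :class:`RawSpectrum`, a
single MALDI-TOF profile spectrum, and :class:`FeatureMatrix`, the samples x
binned-features intensity table produced by preprocessing.  Both are thin
dataclasses over numpy/pandas objects so that every established tool
(sklearn, statsmodels, pandas I/O) can consume them directly.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RawSpectrum", "FeatureMatrix", "feature_label"]


def feature_label(mz: float) -> str:
    """Canonical column label for a feature centered at ``mz`` (Da)."""
    return f"mz_{mz:.4f}"


@dataclass
class RawSpectrum:
    """One profile mass spectrum on a common m/z grid.

    Parameters
    ----------
    mz : ndarray
        Strictly increasing m/z values (Da).
    intensity : ndarray
        Non-negative intensities, same length as ``mz``.
    sample_id : str
        Biological sample identifier (shared across replicate spots).
    batch_id : int
        Detection batch the spectrum was acquired in.
    replicate_idx : int
        Spot replicate index (1-based; samples are spotted in triplicate).
    is_qc : bool
        True for pooled quality-control spectra.
    """

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    batch_id: int = 0
    replicate_idx: int = 1
    is_qc: bool = False

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size >= 2 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def with_intensity(self, intensity: np.ndarray) -> "RawSpectrum":
        """Copy of this spectrum with a new intensity array on the same grid."""
        return replace(self, intensity=np.asarray(intensity, dtype=float))

    def __len__(self) -> int:
        return self.mz.size

    # -- plain-text round trip -------------------------------------------------
    def write_txt(self, path: str | Path) -> None:
        """Write as (optionally gzipped) two-column text: m/z TAB intensity."""
        path = Path(path)
        body = "\n".join(f"{m:.6f}\t{i:.6g}" for m, i in zip(self.mz, self.intensity))
        if path.suffix == ".gz":
            # fixed mtime keeps the archive byte-stable for checksum manifests
            with open(path, "wb") as raw:
                with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as fh:
                    fh.write((body + "\n").encode())
        else:
            path.write_text(body + "\n")

    @classmethod
    def read_txt(cls, path: str | Path, **identity) -> "RawSpectrum":
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        return cls(mz=data[:, 0], intensity=data[:, 1], **identity)

    @classmethod
    def read_mzml(cls, path: str | Path, index: int = 0, **identity) -> "RawSpectrum":
        """Read one spectrum from an mzML file.

        Minimal reader covering profile spectra: 32/64-bit float arrays,
        uncompressed or zlib-compressed, identified by the standard m/z
        (MS:1000514) and intensity (MS:1000515) accessions.
        """
        import base64
        import xml.etree.ElementTree as ET
        import zlib

        ns = "{http://psi.hupo.org/ms/mzml}"
        for i, (_, spec) in enumerate(
            el for el in ET.iterparse(str(path)) if el[1].tag == f"{ns}spectrum"
        ):
            if i != index:
                spec.clear()
                continue
            arrays: dict[str, np.ndarray] = {}
            for bda in spec.iter(f"{ns}binaryDataArray"):
                accessions = {cv.get("accession")
                              for cv in bda.iter(f"{ns}cvParam")}
                dtype = np.float32 if "MS:1000521" in accessions else np.float64
                binary = bda.find(f"{ns}binary")
                raw = base64.b64decode((binary.text or "").strip())
                if "MS:1000574" in accessions:  # zlib compression
                    raw = zlib.decompress(raw)
                data = np.frombuffer(raw, dtype=dtype).astype(float)
                if "MS:1000514" in accessions:
                    arrays["mz"] = data
                elif "MS:1000515" in accessions:
                    arrays["intensity"] = data
            if "mz" not in arrays or "intensity" not in arrays:
                raise ValueError(f"spectrum {index} in {path} lacks m/z or "
                                 "intensity arrays")
            return cls(mz=arrays["mz"], intensity=arrays["intensity"], **identity)
        raise IndexError(f"spectrum index {index} not found in {path}")


@dataclass
class FeatureMatrix:
    """Samples x features intensity table with per-feature provenance.

    ``values`` rows are keyed by sample id (plus replicate index before
    replicate averaging, as a MultiIndex); columns are ``mz_xxx.xxxx`` labels.
    Missing entries (feature not detected in a sample) are NaN until imputed.
    """

    values: pd.DataFrame
    feature_mz: np.ndarray = field(default=None)  # type: ignore[assignment]
    presence: pd.Series | None = None
    qc_cv: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.feature_mz is None:
            self.feature_mz = np.array(
                [float(c.split("_", 1)[1]) for c in self.values.columns]
            )
        self.feature_mz = np.asarray(self.feature_mz, dtype=float)
        if len(self.feature_mz) != self.values.shape[1]:
            raise ValueError("feature_mz length must match number of columns")
        if self.feature_mz.size >= 2 and not np.all(np.diff(self.feature_mz) > 0):
            raise ValueError("feature m/z must be strictly increasing")
        if not self.values.index.is_unique:
            raise ValueError("row keys must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, columns) -> "FeatureMatrix":
        """Restrict to the given feature columns (labels), keeping provenance."""
        cols = list(columns)
        return FeatureMatrix(
            values=self.values[cols],
            feature_mz=np.array([float(c.split("_", 1)[1]) for c in cols]),
            presence=None if self.presence is None else self.presence[cols],
            qc_cv=None if self.qc_cv is None else self.qc_cv.reindex(cols),
        )

    def impute_zero(self) -> "FeatureMatrix":
        """Replace missing entries with 0 (absence = below detection)."""
        out = FeatureMatrix(
            values=self.values.fillna(0.0),
            feature_mz=self.feature_mz.copy(),
            presence=self.presence,
            qc_cv=self.qc_cv,
        )
        return out

    def to_csv(self, path: str | Path, provenance_path: str | Path | None = None) -> None:
        self.values.to_csv(path)
        if provenance_path is not None:
            prov = pd.DataFrame(index=self.values.columns)
            prov["feature_mz"] = self.feature_mz
            if self.presence is not None:
                prov["presence"] = self.presence
            if self.qc_cv is not None:
                prov["qc_cv"] = self.qc_cv
            prov.to_csv(provenance_path, index_label="feature")

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0)
        # replicate-level tables round-trip with a (sample_id, replicate_idx) index
        if df.index.name == "sample_id" and "replicate_idx" in df.columns:
            df = df.set_index("replicate_idx", append=True)
        return cls(values=df)
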