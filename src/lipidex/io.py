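"""Readers and writers for spectra, contact traces and titration series.

Spectra travel as two-column text (m/z, intensity) or mzML; contact traces
and titration series as CSV. The mzML writer emits a minimal
standard-conforming document (uncompressed 64-bit float binary arrays);
reading goes through pyteomics.
"""

from __future__ import annotations

import base64
import struct
import zlib
from pathlib import Path
from xml.etree import ElementTree
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from .competition import TitrationSeries
from .kinetics import ContactTrace
from .spectra import MassSpectrum


# ---------------------------------------------------------------- spectra

def write_spectrum_text(spectrum: MassSpectrum, path) -> None:
    np.savetxt(path, np.column_stack([spectrum.mz, spectrum.intensity]),
               fmt="%.6f\t%.8g", header="mz\tintensity")


def read_spectrum(path, format: str | None = None) -> MassSpectrum:
    """Read a spectrum from two-column text or mzML (auto-detected by suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mzML" if path.suffix.lower() == ".mzml" else "two_column_text"
    if format == "mzML":
        return _read_mzml(path)
    if format != "two_column_text":
        raise ValueError(f"unknown spectrum format {format!r}")
    return _read_two_column(path)


def _read_two_column(path: Path) -> MassSpectrum:
    mz, inten = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                m, i = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
            if mz and m <= mz[-1]:
                raise ValueError(f"{path}:{lineno}: m/z not strictly increasing")
            if i < 0:
                raise ValueError(f"{path}:{lineno}: negative intensity")
            mz.append(m)
            inten.append(i)
    if not mz:
        raise ValueError(f"{path}: empty spectrum file")
    return MassSpectrum(np.array(mz), np.array(inten))


_MZML_TEMPLATE = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="1">
      <spectrum index="0" id="scan=1" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
    </spectrumList>
  </run>
</mzML>
"""


def _encode_doubles(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *values.astype(float))
    return base64.b64encode(raw).decode("ascii")


def write_spectrum_mzml(spectrum: MassSpectrum, path, run_id: str = "run1") -> None:
    mz_b64 = _encode_doubles(spectrum.mz)
    int_b64 = _encode_doubles(spectrum.intensity)
    doc = _MZML_TEMPLATE.format(
        run_id=escape(run_id, {'"': "&quot;"}),
        n=spectrum.mz.size,
        mz_len=len(mz_b64),
        mz_b64=mz_b64,
        int_len=len(int_b64),
        int_b64=int_b64,
    )
    Path(path).write_text(doc)


_NS = "{http://psi.hupo.org/ms/mzml}"

# controlled-vocabulary accessions for binary-array decoding
_ACC_FLOAT64 = "MS:1000523"
_ACC_FLOAT32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _decode_binary_array(node) -> tuple[str | None, np.ndarray]:
    accs = {p.get("accession") for p in node.iter(f"{_NS}cvParam")}
    kind = "mz" if _ACC_MZ_ARRAY in accs else (
        "intensity" if _ACC_INT_ARRAY in accs else None)
    raw = base64.b64decode((node.find(f"{_NS}binary").text or "").strip())
    if _ACC_ZLIB in accs:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_FLOAT32 in accs else "<f8"
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> MassSpectrum:
    # minimal mzML parsing: first spectrum's m/z + intensity arrays
    # (uncompressed or zlib, 32/64-bit float)
    tree = ElementTree.parse(path)
    spectrum_node = tree.getroot().find(f".//{_NS}spectrum")
    if spectrum_node is None:
        raise ValueError(f"{path}: mzML file contains no spectra")
    arrays: dict[str, np.ndarray] = {}
    for bda in spectrum_node.iter(f"{_NS}binaryDataArray"):
        kind, values = _decode_binary_array(bda)
        if kind:
            arrays[kind] = values
    if set(arrays) != {"mz", "intensity"}:
        raise ValueError(f"{path}: spectrum lacks m/z or intensity arrays")
    return MassSpectrum(arrays["mz"], arrays["intensity"])


# ----------------------------------------------------------- contact traces

def write_contact_table(traces: dict[str, ContactTrace], path) -> None:
    """Long-format CSV: frame, site_id, state or distance_nm (uniform kind)."""
    kinds = {t.kind for t in traces.values()}
    if len(kinds) != 1:
        raise ValueError("cannot mix state and distance traces in one table")
    col = "state" if kinds == {"state"} else "distance_nm"
    frames = []
    for site_id, trace in traces.items():
        frames.append(pd.DataFrame({
            "frame": np.arange(trace.n_frames),
            "site_id": site_id,
            col: trace.values,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_contact_table(path, dt: float = 1.0) -> dict[str, ContactTrace]:
    """One ContactTrace per site_id from a long-format CSV.

    Requires columns frame, site_id and exactly one of state / distance_nm;
    frames per site must be 0..n-1 with no holes (constant dt).
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty contact table")
    if not {"frame", "site_id"}.issubset(df.columns):
        raise ValueError(f"{path}: need columns frame, site_id")
    has_state = "state" in df.columns
    has_dist = "distance_nm" in df.columns
    if has_state and has_dist:
        raise ValueError(f"{path}: mixed state and distance_nm columns; use one")
    if not (has_state or has_dist):
        raise ValueError(f"{path}: need a state or distance_nm column")
    col, kind = ("state", "state") if has_state else ("distance_nm", "distance")
    traces = {}
    for site_id, grp in df.groupby("site_id", sort=True):
        frames = grp["frame"].to_numpy()
        if not np.array_equal(np.sort(frames), np.arange(len(frames))):
            raise ValueError(
                f"{path}: site {site_id!r} has missing or non-uniform frames"
            )
        values = grp.sort_values("frame")[col].to_numpy()
        traces[str(site_id)] = ContactTrace(str(site_id), dt, values, kind=kind)
    return traces


# --------------------------------------------------------- titration series

def write_titration_csv(series: TitrationSeries, path) -> None:
    df = series.data.copy()
    df.insert(0, "lipid_conc", series.lipid_conc)
    df.to_csv(path, index=False)


def read_titration_csv(path, lipid_conc: float | None = None) -> TitrationSeries:
    """Columns: detergent_conc, label (or lipid_class), bound_fraction
    [, lipid_conc]."""
    df = pd.read_csv(path)
    if "label" not in df.columns and "lipid_class" in df.columns:
        df = df.rename(columns={"lipid_class": "label"})
    if lipid_conc is None:
        if "lipid_conc" not in df.columns:
            raise ValueError(f"{path}: lipid_conc column or argument required")
        vals = df["lipid_conc"].unique()
        if len(vals) != 1:
            raise ValueError(f"{path}: lipid_conc must be constant over a series")
        lipid_conc = float(vals[0])
    return TitrationSeries(
        df[["detergent_conc", "label", "bound_fraction"]], lipid_conc=lipid_conc
    )
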