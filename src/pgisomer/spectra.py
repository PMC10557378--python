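"""Centroided mzML I/O and diagnostic product-ion channel extraction.

Both the reader and the writer are compact lxml-based implementations
covering the subset of mzML this pipeline works with: centroided scans,
64/32-bit float binary arrays (plain or zlib-compressed), scan start times,
MSⁿ precursor-isolation chains and analyzer metadata.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence
from xml.sax.saxutils import escape

import numpy as np
from lxml import etree

__all__ = [
    "MassSpectrum",
    "ProductIonChannel",
    "TripletAbundance",
    "read_spectra",
    "write_mzml",
    "select_scans",
    "extract_channel",
    "average_fia",
    "ion_trap_channels",
]

HIGH_RES = "high_res"
LOW_RES = "low_res"


@dataclass
class MassSpectrum:
    """One centroided scan.

    ``precursor_chain`` is the ordered list of isolation m/z leading to this
    scan: empty for MS¹, (459.13,) for MS², (459.13, 441.12) for MS³.
    """

    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1
    precursor_chain: tuple[float, ...] = ()
    scan_time: float = 0.0  # seconds from run start
    analyzer: str = HIGH_RES

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.precursor_chain = tuple(float(x) for x in self.precursor_chain)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz array must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.ms_level != len(self.precursor_chain) + 1:
            raise ValueError(
                f"ms_level {self.ms_level} inconsistent with precursor chain "
                f"of length {len(self.precursor_chain)}"
            )
        if self.analyzer not in (HIGH_RES, LOW_RES):
            raise ValueError(f"analyzer must be {HIGH_RES!r} or {LOW_RES!r}")

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass(frozen=True)
class ProductIonChannel:
    """A target m/z with an extraction tolerance.

    ``tol_mode`` is ``"ppm"`` (orbitrap-style, default 5 ppm) or ``"amu"``
    (ion-trap-style, default 0.4 amu).  ``ms_level`` says which scan type the
    channel is read from when scans are interlaced (e.g. SIM precursor
    channels live in MS¹ scans, diagnostic fragments in MS³ scans).
    """

    label: str
    target_mz: float
    tol_mode: str = "amu"
    tol_value: float = 0.4
    ms_level: int = 3

    def __post_init__(self):
        if self.tol_mode not in ("ppm", "amu"):
            raise ValueError("tol_mode must be 'ppm' or 'amu'")
        if self.tol_value <= 0:
            raise ValueError("tol_value must be positive")
        if self.target_mz <= 0:
            raise ValueError("target_mz must be positive")

    @property
    def window(self) -> tuple[float, float]:
        if self.tol_mode == "ppm":
            half = self.target_mz * self.tol_value * 1e-6
        else:
            half = self.tol_value
        return (self.target_mz - half, self.target_mz + half)


def default_tolerance(analyzer: str) -> tuple[str, float]:
    """Analyzer-appropriate tolerance: 5 ppm high-res, 0.4 amu ion trap."""
    return ("ppm", 5.0) if analyzer == HIGH_RES else ("amu", 0.4)


@dataclass
class TripletAbundance:
    """Intensities of the three diagnostic MS³ channels (m/z 331/333/341).

    Relative abundances are each channel's intensity divided by the sum of
    all three; undefined (``defined == False``) when the total is zero.
    """

    i331: float
    i333: float
    i341: float
    n_scans: int = 1

    def __post_init__(self):
        if min(self.i331, self.i333, self.i341) < 0:
            raise ValueError("channel intensities must be non-negative")

    @property
    def total(self) -> float:
        return self.i331 + self.i333 + self.i341

    @property
    def defined(self) -> bool:
        return self.total > 0

    @property
    def r331(self) -> float:
        return self.i331 / self.total if self.defined else float("nan")

    @property
    def r333(self) -> float:
        return self.i333 / self.total if self.defined else float("nan")

    @property
    def r341(self) -> float:
        return self.i341 / self.total if self.defined else float("nan")


def ion_trap_channels() -> list[ProductIonChannel]:
    """The three diagnostic MS³ channels at ion-trap tolerance (±0.4 amu)."""
    return [
        ProductIonChannel("331", 331.0096, "amu", 0.4, ms_level=3),
        ProductIonChannel("333", 333.2060, "amu", 0.4, ms_level=3),
        ProductIonChannel("341", 341.0301, "amu", 0.4, ms_level=3),
    ]


# ---------------------------------------------------------------------------
# mzML reading

_NS = "{http://psi.hupo.org/ms/mzml}"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(element) -> dict[str, str]:
    """name → value of all cvParam/userParam children (one level deep)."""
    out = {}
    for child in element:
        if _local(child.tag) in ("cvParam", "userParam"):
            out[child.get("name", "")] = child.get("value", "")
    return out


def _iter_named(element, name):
    return (c for c in element.iter() if _local(c.tag) == name)


def _decode_binary_array(bda) -> np.ndarray:
    params = {p.get("name") for p in _iter_named(bda, "cvParam")}
    text = next(_iter_named(bda, "binary")).text or ""
    raw = base64.b64decode(text)
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if "32-bit float" in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(elem) -> MassSpectrum:
    params = _cv_params(elem)
    if "profile spectrum" in params:
        raise ValueError(
            f"profile-mode scan {elem.get('id')!r}; centroid the data first "
            "(e.g. msconvert with the peakPicking filter)"
        )
    level = int(params.get("ms level", 1))

    scan_time = 0.0
    filter_string = ""
    for scan in _iter_named(elem, "scan"):
        for p in _iter_named(scan, "cvParam"):
            if p.get("name") == "scan start time":
                scan_time = float(p.get("value"))
                if p.get("unitName") in ("minute", "min"):
                    scan_time *= 60.0
            elif p.get("name") == "filter string":
                filter_string = p.get("value", "")
        break

    chain: list[float] = []
    for prec in _iter_named(elem, "precursor"):
        target = None
        for p in _iter_named(prec, "cvParam"):
            if p.get("name") == "isolation window target m/z":
                target = float(p.get("value"))
                break
            if p.get("name") == "selected ion m/z" and target is None:
                target = float(p.get("value"))
        if target is not None:
            chain.append(target)

    mz = intensity = None
    for bda in _iter_named(elem, "binaryDataArray"):
        names = {p.get("name") for p in _iter_named(bda, "cvParam")}
        if "m/z array" in names:
            mz = _decode_binary_array(bda)
        elif "intensity array" in names:
            intensity = _decode_binary_array(bda)
    if mz is None or intensity is None:
        raise ValueError(f"scan {elem.get('id')!r}: missing m/z or intensity array")

    if "analyzer" in params:
        analyzer = params["analyzer"]
    elif "ITMS" in filter_string:
        analyzer = LOW_RES
    else:
        analyzer = HIGH_RES
    return MassSpectrum(
        mz=mz,
        intensity=intensity,
        ms_level=level,
        precursor_chain=tuple(chain[: level - 1]),
        scan_time=scan_time,
        analyzer=analyzer,
    )


def read_spectra(path: str, analyzer: str | None = None) -> Iterator[MassSpectrum]:
    """Yield every scan of a centroided mzML file as :class:`MassSpectrum`.

    Profile-mode scans are rejected: this pipeline expects data centroided
    upstream (e.g. by msconvert).  ``analyzer`` overrides the analyzer tag
    inferred from file metadata (userParam ``analyzer`` or a Thermo-style
    filter string).  Scans are streamed; the whole file is never held in
    memory.
    """
    context = etree.iterparse(path, events=("end",), tag=f"{_NS}spectrum")
    for _, elem in context:
        s = _parse_spectrum(elem)
        if analyzer is not None:
            s.analyzer = analyzer
        yield s
        elem.clear()


# ---------------------------------------------------------------------------
# mzML writing (minimal, uncompressed 64-bit)


def _b64(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *map(float, values))
    return base64.b64encode(raw).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _spectrum_xml(index: int, s: MassSpectrum) -> str:
    prec_xml = ""
    if s.precursor_chain:
        precs = []
        for target in s.precursor_chain:
            precs.append(
                f"""          <precursor>
            <isolationWindow>
              <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{target}"/>
            </isolationWindow>
            <selectedIonList count="1">
              <selectedIon>
                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{target}"/>
              </selectedIon>
            </selectedIonList>
          </precursor>
"""
            )
        prec_xml = (
            f'        <precursorList count="{len(s.precursor_chain)}">\n'
            + "".join(precs)
            + "        </precursorList>\n"
        )
    mz_b64, int_b64 = _b64(s.mz), _b64(s.intensity)
    return f"""      <spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{s.mz.size}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{s.ms_level}"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <userParam name="analyzer" value="{escape(s.analyzer)}"/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s.scan_time}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
          </scan>
        </scanList>
{prec_xml}        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(int_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""


def write_mzml(spectra: Sequence[MassSpectrum], path: str, run_id: str = "run") -> None:
    """Write centroided scans to a minimal standards-conform mzML file."""
    spectra = list(spectra)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_MZML_HEADER.format(run_id=escape(run_id), count=len(spectra)))
        for i, s in enumerate(spectra):
            fh.write(_spectrum_xml(i, s))
        fh.write(_MZML_FOOTER)


# ---------------------------------------------------------------------------
# Scan selection and channel extraction


def select_scans(
    stream: Iterable[MassSpectrum],
    ms_level: int,
    chain: Sequence[float] = (),
    chain_tol: float = 0.5,
) -> Iterator[MassSpectrum]:
    """Filter a scan stream by MS level and precursor-isolation chain.

    A scan passes when its level matches and every isolation m/z matches the
    requested chain element-wise within ``chain_tol`` (amu).  Order is
    preserved; the output is a subsequence of the input.
    """
    chain = tuple(float(x) for x in chain)
    if len(chain) != ms_level - 1:
        raise ValueError("chain length must be ms_level - 1")
    for s in stream:
        if s.ms_level != ms_level:
            continue
        if len(s.precursor_chain) != len(chain):
            continue
        if all(abs(a - b) <= chain_tol for a, b in zip(s.precursor_chain, chain)):
            yield s


def extract_channel(s: MassSpectrum, ch: ProductIonChannel) -> float:
    """Intensity of the most intense centroid inside the channel window.

    Returns 0 when no peak falls in the window.  The window is half-open with
    inclusive lower bound; among equally intense in-window peaks the one
    nearest the target m/z wins.
    """
    lo, hi = ch.window
    i0 = int(np.searchsorted(s.mz, lo, side="left"))
    i1 = int(np.searchsorted(s.mz, hi, side="left"))
    if i1 <= i0:
        return 0.0
    window_int = s.intensity[i0:i1]
    best = np.flatnonzero(window_int == window_int.max())
    if best.size > 1:
        dist = np.abs(s.mz[i0:i1][best] - ch.target_mz)
        best = best[[int(np.argmin(dist))]]
    return float(window_int[best[0]])


def _auto_window(scans: list[MassSpectrum], duration: float) -> tuple[float, float]:
    """Contiguous window of ``duration`` seconds maximizing total ion current."""
    times = np.array([s.scan_time for s in scans])
    tics = np.array([s.tic for s in scans])
    best_start, best_tic = times[0], -1.0
    for t0 in times:
        in_win = (times >= t0) & (times <= t0 + duration)
        tot = float(tics[in_win].sum())
        if tot > best_tic:
            best_tic, best_start = tot, float(t0)
    return (best_start, best_start + duration)


def average_fia(
    stream: Iterable[MassSpectrum],
    channels: Sequence[ProductIonChannel] | None = None,
    window: tuple[float, float] | None = None,
    duration: float = 2.3 * 60.0,
) -> TripletAbundance:
    """Average the three diagnostic channels over a flow-injection window.

    ``window`` is (start, end) in seconds; when omitted, the contiguous
    window of ``duration`` (default 2.3 min) with the highest summed TIC is
    used, emulating averaging over the electrospray signal of one injection.
    """
    scans = list(stream)
    if not scans:
        raise ValueError("no scans supplied")
    if channels is None:
        channels = ion_trap_channels()
    if len(channels) != 3:
        raise ValueError("exactly three diagnostic channels are required")
    if window is None:
        window = _auto_window(scans, duration)
    t0, t1 = window
    selected = [s for s in scans if t0 <= s.scan_time <= t1]
    if not selected:
        raise ValueError(f"no scans in window [{t0}, {t1}] s")
    means = [float(np.mean([extract_channel(s, ch) for s in selected])) for ch in channels]
    return TripletAbundance(i331=means[0], i333=means[1], i341=means[2], n_scans=len(selected))
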