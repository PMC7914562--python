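"""On-disk formats and run configuration.

The canonical stack format is a multi-page TIFF (one page per time bin,
uint16 auto-promoted to uint32) with a JSON sidecar carrying the
instrument configuration and, when available, the ground-truth phantom.
Becker&Hickl ``.sdt`` files are supported read-only: the reader targets
the publicly documented header layout (42-byte file header, 22-byte block
headers, uncompressed 16-bit data blocks) and fails loudly on anything
else.  A fixture-only writer emits tiny synthetic files in that same
dialect for testing.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import struct
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .types import DecayStack, FiberHdimError, InstrumentConfig, ScenePhantom

__all__ = [
    "RunConfig",
    "read_stack",
    "write_stack",
    "read_label_mask",
    "write_label_mask",
    "read_sdt",
    "write_sdt_fixture",
    "write_manifest",
]


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    analysis: dict = field(default_factory=dict)
    seed: int = 0
    paths: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "instrument": self.instrument.to_dict(),
            "analysis": self.analysis,
            "seed": self.seed,
            "paths": self.paths,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            instrument=InstrumentConfig.from_dict(d.get("instrument", {})),
            analysis=dict(d.get("analysis", {})),
            seed=int(d.get("seed", 0)),
            paths=dict(d.get("paths", {})),
            log_level=str(d.get("log_level", "INFO")),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()[:16]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: DecayStack, path) -> tuple[Path, Path]:
    """Write a DecayStack as multi-page TIFF + JSON sidecar.

    Counts are stored uint16 when they fit, otherwise uint32.
    """
    path = Path(path)
    counts = stack.counts
    if np.issubdtype(counts.dtype, np.floating):
        counts = np.rint(counts).astype(np.int64)
    dtype = np.uint16 if counts.max(initial=0) <= np.iinfo(np.uint16).max else np.uint32
    pages = np.ascontiguousarray(np.moveaxis(counts.astype(dtype), 2, 0))
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "format": "fiberhdim-stack-v1",
        "n_bins": stack.config.n_bins,
        "config": stack.config.to_dict(),
        "truth": stack.truth.to_dict() if stack.truth is not None else None,
    }
    sc_path = _sidecar_path(path)
    with open(sc_path, "w") as fh:
        json.dump(sidecar, fh, sort_keys=True)
    return path, sc_path


def _read_tiff_stack(path: Path) -> DecayStack:
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise FiberHdimError(f"missing JSON sidecar {sc_path}")
    with open(sc_path) as fh:
        try:
            sidecar = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FiberHdimError(f"malformed sidecar {sc_path}: {exc}") from exc
    if "config" not in sidecar:
        raise FiberHdimError(f"sidecar {sc_path} lacks a 'config' section")
    config = InstrumentConfig.from_dict(sidecar["config"])
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != config.n_bins:
        raise FiberHdimError(
            f"TIFF has {pages.shape[0]} pages but sidecar n_bins={config.n_bins}"
        )
    truth = None
    if sidecar.get("truth") is not None:
        truth = ScenePhantom.from_dict(sidecar["truth"])
    counts = np.moveaxis(pages, 0, 2)
    return DecayStack(counts=counts, config=config, truth=truth)


def read_stack(path, config: Optional[InstrumentConfig] = None) -> DecayStack:
    """Read a DecayStack from TIFF+JSON or from a Becker&Hickl SDT file.

    Format is auto-detected from the file magic / extension.  For SDT files
    (which carry no fiber-dispersion metadata) an ``InstrumentConfig`` may
    be supplied; timing fields parsed from the file take precedence.
    """
    path = Path(path)
    if not path.exists():
        raise FiberHdimError(f"no such file: {path}")
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if path.suffix.lower() == ".sdt":
        return read_sdt(path, config=config)
    if magic[:2] in (b"II", b"MM"):
        return _read_tiff_stack(path)
    raise FiberHdimError(f"unrecognised stack format: {path}")


def write_label_mask(mask: np.ndarray, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(mask, dtype=np.int32), photometric="minisblack")
    return path


def read_label_mask(path) -> np.ndarray:
    mask = tifffile.imread(Path(path))
    if mask.ndim != 2:
        raise FiberHdimError("label mask must be a single-page 2-D image")
    return mask.astype(np.int32)


# --------------------------------------------------------------------------
# Becker & Hickl SDT (read-only; fixture writer for the documented dialect)
# --------------------------------------------------------------------------

_SDT_FILE_HEADER = struct.Struct("<hihihihiihhHIHH")  # 42 bytes
# revision, info_offs, info_length, setup_offs, setup_length,
# data_block_offs, no_of_data_blocks, data_block_length,
# meas_desc_block_offs, no_of_meas_desc_blocks, meas_desc_block_length,
# header_valid, reserved1, reserved2, chksum
_SDT_BLOCK_HEADER = struct.Struct("<hiiHhII")
# block_no, data_offs, next_block_offs, block_type, meas_desc_block_no,
# lblock_no, block_length
_SDT_COMPRESSION_MASK = 0x2000
_HEADER_VALID = 0x5555

_SDT_INFO = "fiberhdim synthetic SDT fixture"


def read_sdt(path, config: Optional[InstrumentConfig] = None) -> DecayStack:
    """Read an uncompressed SDT file into a DecayStack.

    Supports one uncompressed 16-bit data block holding an X*Y*T raster
    (geometry taken from the info record written alongside).  Compressed
    or multi-block files raise with the offending block type named.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _SDT_FILE_HEADER.size:
        raise FiberHdimError(f"{path}: too short to be an SDT file")
    (revision, info_offs, info_length, setup_offs, setup_length,
     data_block_offs, n_blocks, data_block_length,
     _mdb_offs, _n_mdb, _mdb_length,
     header_valid, _r1, _r2, _chk) = _SDT_FILE_HEADER.unpack_from(raw, 0)
    if header_valid != _HEADER_VALID:
        raise FiberHdimError(f"{path}: SDT header_valid flag is {header_valid:#x}")
    if n_blocks != 1:
        raise FiberHdimError(f"{path}: expected 1 data block, found {n_blocks}")

    info = raw[info_offs: info_offs + info_length].decode("latin-1", "replace")
    meta: dict[str, str] = {}
    for line in info.splitlines():
        if ":" in line:
            key, _, value = line.partition(":")
            meta[key.strip().lower()] = value.strip()

    (block_no, data_offs, _next_offs, block_type, _mdb_no,
     _lblock_no, block_length) = _SDT_BLOCK_HEADER.unpack_from(raw, data_block_offs)
    if block_type & _SDT_COMPRESSION_MASK:
        raise FiberHdimError(
            f"{path}: compressed SDT data block (type {block_type:#06x}) not supported"
        )
    data = np.frombuffer(raw, dtype="<u2", count=block_length // 2, offset=data_offs)

    try:
        nx = int(meta["scan_x"])
        ny = int(meta["scan_y"])
        nt = int(meta["adc_res"])
    except KeyError as exc:
        raise FiberHdimError(
            f"{path}: info record lacks scan geometry field {exc}"
        ) from exc
    if data.size != nx * ny * nt:
        raise FiberHdimError(
            f"{path}: data block holds {data.size} words, expected {nx * ny * nt}"
        )
    window = float(meta.get("tac_range_ns", 12.5))
    if config is None:
        config = InstrumentConfig(n_bins=nt, window=window)
    else:
        config = config.replace(n_bins=nt, window=window)
    counts = data.reshape(ny, nx, nt).astype(np.uint32)
    return DecayStack(counts=counts, config=config, truth=None)


def write_sdt_fixture(counts: np.ndarray, path, window_ns: float = 12.5) -> Path:
    """Write a tiny synthetic SDT file in the documented uncompressed dialect.

    Fixture/testing aid only — not a general SDT writer.
    """
    counts = np.asarray(counts)
    if counts.ndim != 3:
        raise FiberHdimError("counts must be (Y, X, T)")
    if counts.max(initial=0) > np.iinfo(np.uint16).max:
        raise FiberHdimError("SDT fixture stores 16-bit counts")
    ny, nx, nt = counts.shape
    info = (
        f"{_SDT_INFO}\n"
        f"scan_x: {nx}\nscan_y: {ny}\nadc_res: {nt}\n"
        f"tac_range_ns: {window_ns}\n"
    ).encode("latin-1")
    setup = b"*IDENTIFICATION\n*END\n"
    data = counts.astype("<u2").tobytes()

    info_offs = _SDT_FILE_HEADER.size
    setup_offs = info_offs + len(info)
    mdb_offs = setup_offs + len(setup)
    block_header_offs = mdb_offs  # no measurement description blocks
    data_offs = block_header_offs + _SDT_BLOCK_HEADER.size

    header = _SDT_FILE_HEADER.pack(
        0x0B, info_offs, len(info), setup_offs, len(setup),
        block_header_offs, 1, len(data),
        mdb_offs, 0, 0,
        _HEADER_VALID, 0, 0, 0,
    )
    block_header = _SDT_BLOCK_HEADER.pack(1, data_offs, 0, 0x0000, 0, 1, len(data))
    path = Path(path)
    path.write_bytes(header + info + setup + block_header + data)
    return path


def write_manifest(out_dir, run_config: RunConfig, started: float,
                   extra: Optional[dict] = None) -> Path:
    """Write the run manifest: config hash, seed, versions, wall time."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": run_config.config_hash(),
        "seed": run_config.seed,
        "wall_time_s": round(time.time() - started, 3),
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "fiberhdim": _package_version(),
        },
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "run_manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("fiberhdim")
    except Exception:
        return "unknown"
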