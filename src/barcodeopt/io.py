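"""Parameter files, look-up-table files, and barcode set readers/writers.

Configuration lives in plain-text ``key = value`` files, one file per role
(``param_general`` for l and N, ``param_alpha`` for alpha, ``param_GCC`` ..
``param_CP`` for the penalty-curve constants, ``param_weights`` for the five
weights). ``#`` starts a comment; unknown or duplicate keys are rejected.
Resolution order is built-in defaults < parameter files < explicit
overrides (CLI flags).

Barcode sets round-trip through a versioned text format whose header
carries the barcode length, the set size, and the six penalty totals,
followed by the barcodes in lexicographic order (A < C < G < T). The reader
also accepts bare one-per-line lists and FASTA.

The Hamming look-up tables (hd2_table/hd3_table/hd4_table) are regenerated
in milliseconds, so the files are an optional cache rather than a required
input; they serialize losslessly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO

from . import factors
from .factors import BASES, HdLookupTables, validate_sequence
from .optimizer import OptimizerConfig, SetState
from .penalties import PenaltyParams, Weights

logger = logging.getLogger("barcodeopt")

__all__ = [
    "ConfigError",
    "FormatError",
    "build_hd_luts",
    "read_barcode_list",
    "read_lut_file",
    "read_output",
    "read_params",
    "write_lut_files",
    "write_output",
    "write_params",
]


class ConfigError(ValueError):
    """Invalid or malformed configuration input."""


class FormatError(ValueError):
    """Malformed barcode-set or table file."""


# ---------------------------------------------------------------------------
# key = value parameter files
# ---------------------------------------------------------------------------

# file role -> {key: (target, field, type)}
_GENERAL_KEYS = {"l": ("cfg", "l", int), "N": ("cfg", "n", int)}
_ALPHA_KEYS = {"alpha": ("cfg", "alpha", float)}
_WEIGHT_KEYS = {f"w{i}": ("weights", f"w{i}", float) for i in range(1, 6)}
_PARAM_FILE_KEYS: dict[str, dict[str, tuple[str, str, type]]] = {
    "param_general": _GENERAL_KEYS,
    "param_alpha": _ALPHA_KEYS,
    "param_weights": _WEIGHT_KEYS,
    "param_GCC": {
        k: ("params", f"gcc_{k}", float)
        for k in ("amp", "mu", "sigma", "best_lo", "best_hi", "scale")
    },
    "param_HP": {k: ("params", f"hp_{k}", float) for k in ("b", "c", "offset")},
    "param_SR": {k: ("params", f"sr_{k}", float) for k in ("b", "c", "offset")},
    "param_HD": {
        "amp": ("params", "hd_amp", float),
        "rate": ("params", "hd_rate", float),
        "shift": ("params", "hd_shift", float),
        "zero_from": ("params", "hd_zero_from", int),
    },
    "param_CP": {
        "amp": ("params", "cp_amp", float),
        "rate": ("params", "cp_rate", float),
        "shift": ("params", "cp_shift", float),
        "ref_len": ("params", "cp_ref_len", int),
        "threshold": ("params", "cp_threshold", float),
    },
}


def _parse_kv_file(path: Path, allowed: Mapping[str, tuple]) -> dict[str, str]:
    seen: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path.name}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in allowed:
            raise ConfigError(f"{path.name}:{lineno}: unknown key {key!r}")
        if key in seen:
            raise ConfigError(f"{path.name}:{lineno}: duplicate key {key!r}")
        seen[key] = value
    return seen


def read_params(
    param_dir: str | Path | None,
    overrides: Mapping[str, object] | None = None,
) -> OptimizerConfig:
    """Merge defaults, parameter files and explicit overrides into a config.

    ``overrides`` uses OptimizerConfig field names plus ``weights`` /
    ``params`` fragments (e.g. {"alpha": 0.3, "weights": {"w1": 5}}).
    Missing files fall back to defaults with a logged notice.
    """
    cfg_kw: dict[str, object] = {}
    weight_kw: dict[str, float] = {}
    param_kw: dict[str, object] = {}
    if param_dir is not None:
        d = Path(param_dir)
        if not d.is_dir():
            raise ConfigError(f"parameter directory {d} does not exist")
        for role, allowed in _PARAM_FILE_KEYS.items():
            path = d / role
            if not path.exists():
                logger.info("parameter file %s not found; using defaults", path.name)
                continue
            for key, value in _parse_kv_file(path, allowed).items():
                target, fname, typ = allowed[key]
                try:
                    parsed = typ(value)
                except ValueError as exc:
                    raise ConfigError(
                        f"{path.name}: key {key!r}: cannot parse {value!r} as {typ.__name__}"
                    ) from exc
                {"cfg": cfg_kw, "weights": weight_kw, "params": param_kw}[target][fname] = parsed
    if overrides:
        overrides = dict(overrides)
        weight_kw.update(overrides.pop("weights", None) or {})
        param_kw.update(overrides.pop("params", None) or {})
        cfg_kw.update({k: v for k, v in overrides.items() if v is not None})
    try:
        cfg = OptimizerConfig(
            weights=Weights(**weight_kw),
            params=PenaltyParams(**param_kw),
            **cfg_kw,
        ).validate()
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def write_params(cfg: OptimizerConfig, param_dir: str | Path) -> None:
    """Write a full parameter-file set; round-trips through read_params."""
    d = Path(param_dir)
    d.mkdir(parents=True, exist_ok=True)
    sources = {"cfg": cfg, "weights": cfg.weights, "params": cfg.params}
    for role, allowed in _PARAM_FILE_KEYS.items():
        lines = [f"# {role}: generated by barcodeopt"]
        for key, (target, fname, typ) in allowed.items():
            value = getattr(sources[target], fname)
            lines.append(f"{key} = {value!r}" if isinstance(value, float) else f"{key} = {value}")
        (d / role).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Hamming look-up-table files
# ---------------------------------------------------------------------------

def build_hd_luts() -> HdLookupTables:
    """Exhaustively precomputed Hamming distances for k-mer pairs, k=2,3,4."""
    return HdLookupTables.build()


def _lut_path(directory: Path, k: int) -> Path:
    return directory / f"hd{k}_table"


def write_lut_files(luts: HdLookupTables, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for k, table in luts.tables.items():
        m = 4**k
        kmers = ["".join(BASES[(i >> (2 * (k - 1 - j))) & 3] for j in range(k)) for i in range(m)]
        with open(_lut_path(d, k), "w") as fh:
            for c1 in range(m):
                for c2 in range(m):
                    fh.write(f"{kmers[c1]}\t{kmers[c2]}\t{int(table[(c1 << (2 * k)) | c2])}\n")


def read_lut_file(path: str | Path, k: int) -> np.ndarray:
    path = Path(path)
    m = 4**k
    table = np.full(m * m, 255, dtype=np.uint8)
    count = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        if not raw.strip():
            continue
        parts = raw.split()
        if len(parts) != 3:
            raise FormatError(f"{path.name}:{lineno}: expected 'kmer kmer hd'")
        k1, k2, hd = parts
        if len(k1) != k or len(k2) != k:
            raise FormatError(f"{path.name}:{lineno}: k-mer length != {k}")
        idx = (factors._kmer_code(validate_sequence(k1)) << (2 * k)) | factors._kmer_code(
            validate_sequence(k2)
        )
        table[idx] = int(hd)
        count += 1
    if count != m * m or (table == 255).any():
        raise FormatError(f"{path.name}: expected {m * m} distinct entries, found {count}")
    return table


def read_lut_files(directory: str | Path) -> HdLookupTables:
    d = Path(directory)
    return HdLookupTables(
        tables={k: read_lut_file(_lut_path(d, k), k) for k in HdLookupTables.KS}
    )


# ---------------------------------------------------------------------------
# barcode set files
# ---------------------------------------------------------------------------

_HEADER_FIELDS = ("p_gcct", "p_hpt", "p_srt", "p_hdt", "p_cpt", "p_wt")


def write_output(state: SetState, path: str | Path, weights: Weights | None = None) -> None:
    """Write a barcode set with header (l, N, six penalty totals), barcodes
    sorted lexicographically (A < C < G < T)."""
    weights = weights or Weights()
    totals = state.totals(weights)
    lines = [
        f"# barcode_length = {state.l}",
        f"# n_barcodes = {state.n}",
    ]
    lines += [f"# {name} = {getattr(totals, name)!r}" for name in _HEADER_FIELDS]
    lines += sorted(state.barcodes)
    Path(path).write_text("\n".join(lines) + "\n")


def read_barcode_list(path: str | Path) -> list[str]:
    """Read barcodes from an output file, a bare list, or FASTA.

    All barcodes must share one length and the ACGT alphabet; violations
    raise :class:`FormatError` naming the offending line/record.
    """
    path = Path(path)
    text = path.read_text()
    barcodes: list[str] = []
    if text.lstrip().startswith(">"):
        for record in SeqIO.parse(path, "fasta"):
            try:
                barcodes.append(validate_sequence(str(record.seq)))
            except ValueError as exc:
                raise FormatError(f"{path.name}: record {record.id!r}: {exc}") from exc
    else:
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                barcodes.append(validate_sequence(line))
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: {exc}") from exc
    if not barcodes:
        raise FormatError(f"{path.name}: no barcodes found")
    lengths = {len(b) for b in barcodes}
    if len(lengths) > 1:
        raise FormatError(f"{path.name}: mixed barcode lengths {sorted(lengths)}")
    return barcodes


def read_output(path: str | Path) -> tuple[list[str], dict[str, float]]:
    """Read an output file, returning (barcodes, header metadata)."""
    path = Path(path)
    meta: dict[str, float] = {}
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if line.startswith("#") and "=" in line:
            key, value = (part.strip() for part in line[1:].split("=", 1))
            meta[key] = float(value)
    return read_barcode_list(path), meta


def write_fasta(barcodes: Sequence[str], path: str | Path, prefix: str = "barcode") -> None:
    with open(path, "w") as fh:
        for i, b in enumerate(barcodes, 1):
            fh.write(f">{prefix}_{i}\n{b}\n")
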