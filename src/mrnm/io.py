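"""Text-file formats: two-id phenotype/covariate tables, fit reports, truth sidecars.

Phenotype and covariate files follow the two-id convention (family id,
individual id, value, whitespace separated).  "NA" and -9 are both accepted
as missing on read; "NA" is written.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .reml import FitResult

__all__ = [
    "read_pheno",
    "write_pheno",
    "write_truth",
    "read_truth",
    "write_fit_report",
    "provenance_header",
    "align_ids",
]

MISSING_OUT = "NA"


def read_pheno(path: str | Path) -> pd.DataFrame:
    """Read a two-id phenotype table -> DataFrame(fid, iid, value)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected 'FID IID value', got {line!r}")
            fid, iid, raw = parts[0], parts[1], parts[2]
            if raw.upper() == "NA" or raw == "-9":
                val = np.nan
            else:
                try:
                    val = float(raw)
                except ValueError as exc:
                    raise ValueError(f"{path}:{ln}: bad value {raw!r}") from exc
            rows.append((fid, iid, val))
    return pd.DataFrame(rows, columns=["fid", "iid", "value"])


def write_pheno(path: str | Path, ids, values) -> None:
    with open(path, "w") as fh:
        for iid, v in zip(ids, values):
            out = MISSING_OUT if (v is None or (isinstance(v, float) and np.isnan(v))) else f"{v:.10g}"
            fh.write(f"{iid} {iid} {out}\n")


def write_truth(path: str | Path, params: dict[str, float]) -> None:
    """Sidecar of simulation truth, one `name = value` line per parameter."""
    with open(path, "w") as fh:
        for k, v in params.items():
            fh.write(f"{k} = {v:.10g}\n")


def read_truth(path: str | Path) -> dict[str, float]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if "=" in line:
                k, _, v = line.partition("=")
                out[k.strip()] = float(v)
    return out


def provenance_header(config: dict, seeds) -> str:
    blob = repr(sorted(config.items())).encode()
    h = hashlib.sha256(blob).hexdigest()[:12]
    return (
        f"# mrnm {__version__}\n# config_hash {h}\n# seeds {seeds}\n"
    )


def write_fit_report(path: str | Path, result: FitResult, config: dict | None = None,
                     seeds=None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(config or {}, seeds))
        fh.write("param\testimate\tse\tboundary\n")
        for p in result.spec.params:
            se = result.se.get(p, float("nan"))
            flag = "yes" if result.boundary.get(p) else "no"
            fh.write(f"{p}\t{result.params[p]:.6g}\t{se:.4g}\t{flag}\n")
        fh.write(f"logL\t{result.loglik:.6f}\n")
        fh.write(f"converged\t{result.converged}\n")
        fh.write(f"iterations\t{result.n_iter}\n")


def align_ids(grm_ids: list[str], *tables: pd.DataFrame) -> list[str]:
    """Intersect GRM ids with each table's (fid-insensitive) individual ids.

    The GRM defines the canonical order.  Raises when the intersection is
    empty.
    """
    common = set(grm_ids)
    for t in tables:
        common &= set(t["iid"])
    keep = [i for i in grm_ids if i in common]
    if not keep:
        raise ValueError("no individuals shared between GRM and phenotype files")
    return keep
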