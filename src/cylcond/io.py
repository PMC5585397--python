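"""Tabular I/O and provenance manifests.

Results are plain CSV (header rows name the units: lengths in a, energies in
k_B T) plus a JSON manifest holding the tool version, command, full parameter
echo, seeds, timestamps and file digests, so a run can be reproduced
bit-identically from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .sampling import ChainResult

__all__ = ["write_manifest", "save_chain", "load_chain_tables", "save_grid"]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(outdir: Path, command: str, params: dict,
                   started: str | None = None) -> Path:
    outdir = Path(outdir)
    files = sorted(p for p in outdir.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "tool": "cylcond",
        "version": __version__,
        "command": command,
        "parameters": params,
        "python": platform.python_version(),
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
        "files": {p.name: _digest(p) for p in files},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def save_chain(outdir, chain: ChainResult) -> Path:
    """ChainResult as a directory of CSV + JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()

    pd.DataFrame({"energy_kBT": chain.energies}).to_csv(
        outdir / "energies.csv", index=False)
    pd.DataFrame({"condensed_count": chain.condensed_counts}).to_csv(
        outdir / "counts.csv", index=False)
    centers = 0.5 * (chain.bin_edges[:-1] + chain.bin_edges[1:])
    pd.DataFrame({
        "ln_r_over_R": centers,
        "counts_total": chain.profile_histogram.sum(axis=0),
    }).to_csv(outdir / "histogram.csv", index=False)

    model = chain.model
    params = {
        "model": {"N": model.N, "xi": model.xi, "R_a": model.R, "D_a": model.D,
                  "delta": model.delta, "H_a": model.H, "Xi": model.Xi,
                  "mu_a": model.mu},
        "run": dataclasses.asdict(chain.run_config),
        "seed": chain.seed,
        "step_local_used_a": chain.step_local_used,
        "acceptance": chain.acceptance,
        "units": {"length": "a = q/tau", "energy": "k_B T"},
        "error_method": "Flyvbjerg-Petersen blocking",
    }
    write_manifest(outdir, "simulate", params, started)
    return outdir


def load_chain_tables(outdir) -> dict:
    """Load the CSV tables and manifest of a saved chain directory."""
    outdir = Path(outdir)
    return {
        "energies": pd.read_csv(outdir / "energies.csv"),
        "counts": pd.read_csv(outdir / "counts.csv"),
        "histogram": pd.read_csv(outdir / "histogram.csv"),
        "manifest": json.loads((outdir / "manifest.json").read_text()),
    }


def save_grid(outdir, result, command: str = "grid") -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()
    result.table.to_csv(outdir / "grid.csv", index=False)
    cfg = dataclasses.asdict(result.config)
    params = {"config": cfg, "failures": result.failures,
              "units": {"length": "a = q/tau", "energy": "k_B T"}}
    write_manifest(outdir, command, params, started)
    return outdir
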