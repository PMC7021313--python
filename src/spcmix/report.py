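"""ARL comparison tables and reproducible result I/O.

``build_arl_table`` regenerates benchmark-style tables: one row per shift
size and one column group per chart, each cell carrying (ARL, SE, SDRL,
MRL). Output files embed the package version, the seed, and a hash of the
generating config so any table can be traced back to its inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from typing import Optional

import pandas as pd

from . import __version__
from .charts import make_chart
from .distributions import make_distribution, with_delta
from .runlength import estimate_run_length

__all__ = ["build_arl_table", "config_hash", "write_results", "read_results"]


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serializable config."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def build_arl_table(config: dict) -> pd.DataFrame:
    """Simulate an ARL comparison table from a config dict.

    Expected keys::

        distribution: {family, params, scale_convention?, shift_mode?}
        charts: [{name?, kind, lambda?, w?, H, limit_mode?, smoothing?}, ...]
        deltas: [float, ...]
        n_reps: int, seed: int, max_steps?: int

    Returns a tidy frame with one row per (chart, delta).
    """
    dcfg = config["distribution"]
    base = make_distribution(
        dcfg["family"],
        dcfg["params"],
        delta=0.0,
        scale_convention=dcfg.get("scale_convention", "sd"),
        shift_mode=dcfg.get("shift_mode", "location"),
    )
    deltas = list(config["deltas"])
    if not deltas:
        raise ValueError("deltas must be non-empty")
    n_reps = int(config["n_reps"])
    seed = int(config["seed"])
    max_steps = int(config.get("max_steps", 10_000))
    rows = []
    for i, ccfg in enumerate(config["charts"]):
        chart = make_chart(
            ccfg["kind"],
            lambda_=float(ccfg.get("lambda", ccfg.get("lambda_", 1.0))),
            w=int(ccfg.get("w", 1)),
            H=float(ccfg["H"]),
            center=base.mu0,
            scale=base.sigma0,
            limit_mode=ccfg.get("limit_mode"),
            smoothing=ccfg.get("smoothing", "ma"),
        )
        name = ccfg.get("name", chart.kind)
        for j, d in enumerate(deltas):
            run_seed = (seed + 100_003 * i + 1_009 * j) % 2**31
            summ = estimate_run_length(chart, with_delta(base, d), n_reps, run_seed, max_steps)
            rows.append({"chart": name, **{k: v for k, v in asdict(summ).items()}, "delta": d})
    df = pd.DataFrame(rows)
    return df[
        ["chart", "delta", "arl", "se_arl", "sdrl", "mrl", "n_reps", "n_censored", "max_steps", "seed"]
    ]


def write_results(path, table: pd.DataFrame, config: Optional[dict] = None) -> None:
    """Write a results table as CSV with a provenance header."""
    lines = [f"# spcmix {__version__}"]
    if config is not None:
        lines.append(f"# seed={config.get('seed')} config_hash={config_hash(config)}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
        table.to_csv(fh, index=False)


def read_results(path) -> pd.DataFrame:
    """Read a table written by :func:`write_results` (header lines skipped)."""
    return pd.read_csv(path, comment="#")
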