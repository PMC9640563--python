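"""Figure and manifest emission for evaluation runs.

Plots are regenerated from the result CSVs (never from in-memory state) so
every figure can be rebuilt from a run directory alone.  Each run writes a
manifest recording the configuration hash, seed and package versions;
timestamps are recorded but excluded from the hash.
"""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

MODEL_STYLE = {
    "OLSLR": dict(color="black", marker="o"),
    "EXPONENTIAL": dict(color="tab:green", marker="s"),
    "QUADRATIC": dict(color="tab:red", marker="^"),
    "M_ROBUST": dict(color="tab:blue", marker="D"),
    "LOGISTIC": dict(color="tab:purple", marker="v"),
}


def plot_mae_curves(cells_csv: str | Path, saturation_csv: str | Path,
                    outdir: str | Path, subgroup: str = "overall") -> list[Path]:
    """Mean error vs. window length, one panel per (analysis path, horizon).

    The dashed line marks the upper 95 % confidence bound of the best
    reference-model cell — the saturation threshold.
    """
    cells = pd.read_csv(cells_csv)
    sat = pd.read_csv(saturation_csv)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    sub = cells[cells["subgroup"] == subgroup]
    for (path, horizon), g in sub.groupby(["analysis_path", "horizon"]):
        fig, ax = plt.subplots(figsize=(5.5, 4))
        for model, mg in g.groupby("model"):
            mg = mg.sort_values("n_used")
            style = MODEL_STYLE.get(model, {})
            ax.errorbar(mg["n_used"], mg["mean_mae"], yerr=1.96 * mg["se_mae"],
                        label=model, capsize=2, **style)
        line = sat[(sat["analysis_path"] == path) & (sat["horizon"] == horizon)
                   & (sat["subgroup"] == subgroup)]
        if not line.empty:
            ax.axhline(float(line["ci_upper"].iloc[0]), ls="--", color="gray",
                       label="95% CI of best OLSLR")
        ax.set_xlabel("number of VFs used")
        ylabel = "MAE (dB)" if path == "PW" else "MS absolute error (dB)"
        ax.set_ylabel(ylabel)
        ax.set_title(f"{path} prediction, horizon {horizon} ({subgroup})")
        ax.legend(fontsize=7)
        fig.tight_layout()
        for ext in ("png", "svg"):
            f = outdir / f"mae_{path.lower()}_h{horizon}_{subgroup}.{ext}"
            fig.savefig(f, dpi=150)
            written.append(f)
        plt.close(fig)
    return written


def _config_hash(config_text: str, seed: int | None) -> str:
    h = hashlib.sha256()
    h.update(config_text.encode())
    h.update(str(seed).encode())
    return h.hexdigest()[:16]


def write_manifest(outdir: str | Path, config_text: str = "",
                   seed: int | None = None, extra: dict | None = None) -> Path:
    import vftrend

    manifest = {
        "config_hash": _config_hash(config_text, seed),
        "seed": seed,
        "vftrend_version": vftrend.__version__,
        "python": platform.python_version(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    if extra:
        manifest.update(extra)
    path = Path(outdir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
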