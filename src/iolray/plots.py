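"""Report figures: AE bars, AE by axial-length bin, within-threshold
percentages, and PE/AE scatter against axial length."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .analysis import AL_BIN_LABELS, THRESHOLDS  # noqa: E402


def save_report_figures(errors: pd.DataFrame, outdir: str | Path
                        ) -> list[Path]:
    """Write the five standard comparison figures as PNG files.

    ``errors`` is the long prediction-error table produced by
    :func:`iolray.synthetic.predict_all_methods`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    formulas = sorted(errors["formula"].unique())
    paths = []

    fig, ax = plt.subplots(figsize=(6, 4))
    means = [errors.loc[errors["formula"] == f, "ae"].mean()
             for f in formulas]
    sds = [errors.loc[errors["formula"] == f, "ae"].std(ddof=1)
           for f in formulas]
    ax.bar(formulas, means, yerr=sds, capsize=3)
    ax.set_ylabel("Mean absolute prediction error (D)")
    paths.append(_save(fig, outdir / "fig1_mean_ae.png"))

    fig, ax = plt.subplots(figsize=(7, 4))
    present = [b for b in AL_BIN_LABELS if (errors["al_bin"] == b).any()]
    width = 0.8 / max(len(formulas), 1)
    for j, f in enumerate(formulas):
        sub = errors[errors["formula"] == f]
        vals = [sub.loc[sub["al_bin"] == b, "ae"].mean() for b in present]
        ax.bar([i + j * width for i in range(len(present))], vals,
               width=width, label=f)
    ax.set_xticks([i + 0.4 for i in range(len(present))], present)
    ax.set_xlabel("Axial length (mm)")
    ax.set_ylabel("Mean absolute error (D)")
    ax.legend(fontsize=8)
    paths.append(_save(fig, outdir / "fig2_ae_by_al.png"))

    fig, ax = plt.subplots(figsize=(6, 4))
    for f in formulas:
        ae = errors.loc[errors["formula"] == f, "ae"]
        pct = [(ae <= t).mean() * 100 for t in THRESHOLDS]
        ax.plot([str(t) for t in THRESHOLDS], pct, marker="o", label=f)
    ax.set_xlabel("Threshold (D)")
    ax.set_ylabel("% of eyes within predicted refraction")
    ax.legend(fontsize=8)
    paths.append(_save(fig, outdir / "fig3_pct_within.png"))

    for col, name in (("ae", "fig4_ae_scatter.png"),
                      ("pe", "fig5_pe_scatter.png")):
        fig, ax = plt.subplots(figsize=(7, 4))
        for f in formulas:
            sub = errors[errors["formula"] == f]
            ax.scatter(sub["al"], sub[col], s=6, alpha=0.5, label=f)
        ax.set_xlabel("Axial length (mm)")
        ax.set_ylabel(f"{col.upper()} (D)")
        ax.legend(fontsize=8, markerscale=2)
        paths.append(_save(fig, outdir / name))
    return paths


def _save(fig, path: Path) -> Path:
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
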