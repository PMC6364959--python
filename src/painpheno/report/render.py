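"""Human-readable table rendering from machine-readable stage outputs.

Every rendered number is a formatted copy of a value already present in
a stage output file — no statistics are recomputed here.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .format import fmt_count_pct

GROUP_ORDER = ("SSRI+/Pro+", "SSRI+/Pro-", "SSRI-/Pro+", "SSRI-/Pro-")


def render_group_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Group sizes in the "n (%)" convention (baseline table analogue)."""
    total = len(cohort)
    rows = []
    for group in GROUP_ORDER:
        count = int((cohort["group"] == group).sum())
        rows.append(
            {
                "group": group,
                "n_pct": fmt_count_pct(count, total) if total else "0 (0.0)",
            }
        )
    return pd.DataFrame(rows)


def render_reports(run_dir: str | Path, plots: bool = False) -> dict[str, Path]:
    """Render formatted tables (and optionally figures) for a run."""
    run = Path(run_dir)
    report_dir = run / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    cohort_path = run / "cohort" / "cohort.csv"
    if cohort_path.exists():
        cohort = pd.read_csv(cohort_path)
        table2 = render_group_table(cohort)
        path = report_dir / "table2_groups.txt"
        path.write_text(table2.to_string(index=False) + "\n", encoding="utf-8")
        written["table2"] = path

    for name in ("table3_report", "table4_report"):
        src = run / "outcomes" / f"{name}.csv"
        if src.exists():
            df = pd.read_csv(src)
            path = report_dir / f"{name}.txt"
            path.write_text(df.round(3).to_string(index=False) + "\n", encoding="utf-8")
            written[name] = path

    cv_path = run / "predict" / "cv_results.json"
    if cv_path.exists():
        payload = json.loads(cv_path.read_text(encoding="utf-8"))
        lines = ["mean (SD) fold AUC per time point"]
        for tp, entry in sorted(payload.items()):
            lines.append(f"  {tp}: {entry['mean_auc']:.2f} (+/-{entry['mean_auc_sd']:.2f})")
        path = report_dir / "auc_summary.txt"
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written["auc_summary"] = path

    if plots:
        written.update(_render_plots(run, report_dir))
    return written


def _render_plots(run: Path, report_dir: Path) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: dict[str, Path] = {}
    roc_path = run / "predict" / "roc_points.csv"
    if roc_path.exists():
        roc = pd.read_csv(roc_path)
        for tp, sub in roc.groupby("time_point"):
            fig, ax = plt.subplots(figsize=(4, 4))
            for fold, curve in sub.groupby("fold"):
                if fold == "mean":
                    ax.plot(curve["fpr"], curve["tpr"], color="black", lw=2, label="mean")
                else:
                    ax.plot(curve["fpr"], curve["tpr"], alpha=0.3, lw=0.8)
            ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
            ax.set_xlabel("false positive rate")
            ax.set_ylabel("true positive rate")
            ax.set_title(f"ROC, {tp}")
            ax.legend(loc="lower right")
            path = report_dir / f"roc_{tp}.png"
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
            written[f"roc_{tp}"] = path
    coef_path = run / "predict" / "coefficients.csv"
    if coef_path.exists():
        coef = pd.read_csv(coef_path)
        for tp, sub in coef.groupby("time_point"):
            top = sub.nsmallest(15, "rank").iloc[::-1]
            fig, ax = plt.subplots(figsize=(5, 4))
            ax.barh(top["feature"], top["coefficient"])
            ax.set_xlabel("coefficient")
            ax.set_title(f"top coefficients, {tp}")
            path = report_dir / f"coefficients_{tp}.png"
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
            written[f"coefficients_{tp}"] = path
    return written
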