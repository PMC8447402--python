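"""Figure helpers: risk-curve panels, delay-vs-budget curves, delay boxes."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .evaluation import DelayEvaluation
from .hazard import MonthlyRiskProfile


def plot_risk_profiles(
    profiles: dict[str, MonthlyRiskProfile], path: str | Path | None = None
):
    """Two panels: cumulative progression risk and each month's probability."""
    fig, (ax_cum, ax_mass) = plt.subplots(1, 2, figsize=(10, 4))
    for name, prof in profiles.items():
        months = np.arange(prof.horizon + 1)
        ax_cum.plot(months, prof.cumulative * 100, label=name)
        ax_mass.plot(np.arange(1, prof.horizon + 1), prof.mass * 100, label=name)
    ax_cum.set_xlabel("months since complete response")
    ax_cum.set_ylabel("cumulative progression probability (%)")
    ax_mass.set_xlabel("month")
    ax_mass.set_ylabel("monthly progression probability (%)")
    for ax in (ax_cum, ax_mass):
        ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_delay_vs_budget(sweep: pd.DataFrame, path: str | Path | None = None):
    """Total delayed-detection months against visit budget, controls as points."""
    fig, ax = plt.subplots(figsize=(6, 4))
    risk = sweep[sweep["name"].str.contains("_k")]
    ctrl = sweep[~sweep["name"].str.contains("_k")]
    ax.plot(risk["budget"], risk["total_delay_months"], "o-", color="steelblue",
            label="risk-based schedule")
    for _, row in ctrl.iterrows():
        ax.plot(row["budget"], row["total_delay_months"], "s", color="firebrick")
        ax.annotate(row["name"], (row["budget"], row["total_delay_months"]),
                    textcoords="offset points", xytext=(5, 5))
    ax.set_xlabel("number of follow-up visits")
    ax.set_ylabel("total delayed-detection months")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_delay_boxes(
    evaluations: dict[str, DelayEvaluation], path: str | Path | None = None
):
    """Per-patient delay distributions for competing schedules."""
    fig, ax = plt.subplots(figsize=(5, 4))
    labels = list(evaluations)
    data = [list(evaluations[k].per_patient_delay.values()) for k in labels]
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("delayed-detection months per patient")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
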