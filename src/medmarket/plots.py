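"""Figure panels for sweeps, per-pair reports and scenarios."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .experiments import SweepResult


def _axes(n_panels: int):
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, n_panels, figsize=(4.2 * n_panels, 3.4))
    return fig, np.atleast_1d(axes)


def plot_doctor_count_sweep(sweep: SweepResult):
    """Three panels: doctor waits, patient waits, utilizations vs n."""
    fig, ax = _axes(3)
    x = sweep.records.index.to_numpy(dtype=float)
    r = sweep.records
    ax[0].plot(x, r["doctor_wait_mode1"], "o-", label="mode 1")
    ax[0].plot(x, r["doctor_wait_mode2_mean"], "s-", label="mode 2")
    ax[0].set_ylabel("doctor wait (h)")
    ax[1].plot(x, r["patient_wait_mode1"], "o-", label="mode 1")
    ax[1].plot(x, r["patient_wait_mode2"], "s-", label="mode 2")
    ax[1].set_ylabel("patient wait (h)")
    ax[2].plot(x, r["utilization_mode1"], "o-", label="mode 1")
    ax[2].plot(x, r["utilization_mode2"], "s-", label="mode 2")
    ax[2].plot(x, r["utilization_avg"], "k--", label="average")
    ax[2].set_ylabel("utilization")
    for a in ax:
        a.set_xlabel("number of doctors")
        a.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_parameter_sweep(sweep: SweepResult):
    """Doctor and patient waits against the swept parameter."""
    fig, ax = _axes(2)
    x = sweep.records.index.to_numpy(dtype=float)
    r = sweep.records
    ax[0].plot(x, r["doctor_wait_mode1"], "o-", label="mode 1")
    ax[0].plot(x, r["doctor_wait_mode2_mean"], "s-", label="mode 2")
    ax[0].set_ylabel("doctor wait (h)")
    ax[1].plot(x, r["patient_wait_mode1"], "o-", label="mode 1")
    ax[1].plot(x, r["patient_wait_mode2"], "s-", label="mode 2")
    ax[1].set_ylabel("patient wait (h)")
    for a in ax:
        a.set_xlabel(sweep.parameter)
        a.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_per_pair(report: pd.DataFrame):
    """Bar chart of per-group doctor waits (app pairs + 'non-app')."""
    fig, ax = _axes(1)
    ax[0].bar(report["group"], report["doctor_wait"])
    ax[0].set_ylabel("doctor wait (h)")
    ax[0].tick_params(axis="x", rotation=60)
    fig.tight_layout()
    return fig


def plot_scenarios(table: pd.DataFrame):
    """Average doctor and patient waits per scenario."""
    fig, ax = _axes(2)
    ax[0].bar(table.index, table["avg_doctor_wait"])
    ax[0].set_ylabel("avg doctor wait (h)")
    ax[1].bar(table.index, table["avg_patient_wait"])
    ax[1].set_ylabel("avg patient wait (h)")
    for a in ax:
        a.tick_params(axis="x", rotation=20)
    fig.tight_layout()
    return fig
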