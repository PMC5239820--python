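"""SAMPL-style error metrics for binding free energy predictions.

Given per-system calculated and experimental binding free energies grouped
by host, these are the standard challenge metrics: the average signed error
(AvErr), the mean absolute deviation (MAD), the mean absolute deviation
after translation by the signed error (MADTr, which scores relative free
energies), the squared Pearson correlation R^2, and the equal-affinity
"dummy" predictor whose MADTr is the mean absolute deviation of the
experimental values from their mean.

A prediction table for the SAMPL5 octa-acid series (hosts OAH and OAMe,
guests G1-G6, with the ITC/NMR consensus experimental values) ships with
the package; the OAH-Gu2 complex it contains is a calibration reference and
is excluded from all metric groups.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "PredictionTable",
    "load_sampl5_octa_acid",
    "prediction_table",
    "av_err",
    "mad",
    "mad_tr",
    "r_squared",
    "dummy_madtr",
    "metric_uncertainty",
    "COMBINED",
]

#: group label meaning "all hosts pooled"
COMBINED = "combined"


class PredictionTable:
    """Per-system calculated vs experimental binding free energies.

    Wraps a DataFrame with columns ``system``, ``host``, ``dg_calc``,
    ``dg_exp`` and optional ``dg_err``; system ids must be unique.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"system", "host", "dg_calc", "dg_exp"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if df["system"].duplicated().any():
            raise ValueError("duplicated system ids")
        if len(df) == 0:
            raise ValueError("empty prediction table")
        self.df = df.reset_index(drop=True)

    def group(self, group: str) -> pd.DataFrame:
        if group == COMBINED:
            return self.df
        sub = self.df[self.df["host"] == group]
        if len(sub) == 0:
            raise ValueError(f"no systems in group {group!r}")
        return sub

    @property
    def has_errors(self) -> bool:
        return "dg_err" in self.df.columns and self.df["dg_err"].notna().all()


def load_sampl5_octa_acid() -> pd.DataFrame:
    """Load the packaged SAMPL5 octa-acid prediction sets.

    Wide format: one row per system with the submitted-GAFF, refined-GAFF
    and refined-OPLS predictions, their error estimates, and the
    experimental consensus value.  Rows with role ``reference`` (OAH-Gu2)
    are calibration-only and are dropped by :func:`prediction_table`.
    """
    with resources.files("funnelbind.data").joinpath(
            "oa_sampl5_predictions.csv").open() as fh:
        return pd.read_csv(fh)


def prediction_table(df: pd.DataFrame | None = None,
                     prediction_set: str = "gaff_refined") -> PredictionTable:
    """Tidy one prediction set out of the wide octa-acid table.

    ``prediction_set`` is one of ``gaff_submitted``, ``gaff_refined``,
    ``opls_refined``.  Reference-only systems are excluded.
    """
    if df is None:
        df = load_sampl5_octa_acid()
    col = f"dg_{prediction_set}"
    if col not in df.columns:
        raise ValueError(f"unknown prediction set {prediction_set!r}")
    df = df[df["role"] != "reference"] if "role" in df.columns else df
    out = pd.DataFrame({
        "system": df["system"],
        "host": df["host"],
        "dg_calc": df[col],
        "dg_exp": df["dg_exp"],
    })
    err_col = f"err_{prediction_set}"
    if err_col in df.columns:
        out["dg_err"] = df[err_col]
    return PredictionTable(out)


def av_err(table: PredictionTable, group: str = COMBINED) -> float:
    """Average signed error mean(dg_calc - dg_exp) over the group."""
    sub = table.group(group)
    return float((sub["dg_calc"] - sub["dg_exp"]).mean())


def mad(table: PredictionTable, group: str = COMBINED) -> float:
    """Mean absolute deviation mean|dg_calc - dg_exp| over the group."""
    sub = table.group(group)
    return float((sub["dg_calc"] - sub["dg_exp"]).abs().mean())


def mad_tr(table: PredictionTable, group: str = COMBINED) -> float:
    """Mean absolute deviation after subtracting the group's signed error.

    Translation-invariant: adding any constant to all predictions leaves it
    unchanged, so it scores relative binding free energies.
    """
    sub = table.group(group)
    err = sub["dg_calc"] - sub["dg_exp"]
    return float((err - err.mean()).abs().mean())


def r_squared(table: PredictionTable, group: str = COMBINED) -> float:
    """Squared Pearson correlation between predictions and experiment."""
    sub = table.group(group)
    if len(sub) < 3:
        raise ValueError("need at least 3 systems for a correlation")
    if sub["dg_calc"].nunique() == 1 or sub["dg_exp"].nunique() == 1:
        raise ValueError("constant column: correlation undefined")
    r = np.corrcoef(sub["dg_calc"], sub["dg_exp"])[0, 1]
    return float(r * r)


def dummy_madtr(table: PredictionTable, group: str = COMBINED) -> float:
    """MADTr of the equal-affinity dummy predictor.

    Equal predictions make MADTr collapse to mean|dg_exp - mean(dg_exp)|,
    the natural baseline any real prediction set should beat.
    """
    sub = table.group(group)
    e = sub["dg_exp"]
    return float((e - e.mean()).abs().mean())


_METRICS = {"av_err": av_err, "mad": mad, "mad_tr": mad_tr,
            "r_squared": r_squared}


def metric_uncertainty(table: PredictionTable, group: str = COMBINED,
                       n_rep: int = 1000, seed: int | None = None,
                       metrics: tuple[str, ...] = ("mad", "mad_tr", "av_err",
                                                   "r_squared")) -> dict:
    """Monte-Carlo spread of the metrics under the per-system errors.

    Each replicate perturbs every prediction by Gaussian noise with that
    system's reported standard error and recomputes the metrics; returns
    ``{metric: {"mean": ..., "std": ...}}`` over ``n_rep`` replicates.
    """
    if not table.has_errors:
        raise ValueError("per-system errors required for metric_uncertainty")
    rng = np.random.default_rng(seed)
    base = table.df
    samples = {name: np.empty(n_rep) for name in metrics}
    for i in range(n_rep):
        noisy = base.copy()
        noisy["dg_calc"] = base["dg_calc"] + rng.standard_normal(len(base)) \
            * base["dg_err"].to_numpy()
        pert = PredictionTable(noisy)
        for name in metrics:
            samples[name][i] = _METRICS[name](pert, group)
    return {name: {"mean": float(v.mean()), "std": float(v.std(ddof=1))}
            for name, v in samples.items()}
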