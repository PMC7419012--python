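"""End-to-end orchestration and the small bespoke statistics.

The pipeline ties together: neuron selection by drug-induced rate change,
conductance estimation, population metrics (synchrony, dimensionality) and
chaos metrics, and writes delimited-text tables plus a JSON summary.  The
heavier statistics the analysis calls for (quadratic-vs-linear regression
with BIC and a likelihood-ratio test; Cook's-distance outlier flagging) are
implemented here on top of statsmodels.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import SpikeDataset

__all__ = [
    "select_neurons_by_rate_change",
    "inverted_u_test",
    "cooks_outliers",
    "RunConfig",
    "run_pipeline",
]


def select_neurons_by_rate_change(
    control: SpikeDataset, drug: SpikeDataset,
    direction: str, threshold: float = 0.5,
) -> list[int]:
    """Neurons whose firing rate changed enough under the drug.

    direction='decrease' (gap-junction blocker) keeps neurons whose drug rate
    is <= (1 - threshold) x control; direction='increase' (GABA-A blocker)
    keeps rate >= (1 + threshold) x control.  Zero-rate control neurons are
    excluded with a warning (undefined ratio).
    """
    import warnings

    if direction not in ("decrease", "increase"):
        raise ValueError("direction must be 'decrease' or 'increase'")
    if set(control.trains) != set(drug.trains):
        raise ValueError("neuron ids differ between control and drug datasets")
    kept = []
    for nid in control.neuron_ids:
        rc = len(control.trains[nid]) / control.duration
        rd = len(drug.trains[nid]) / drug.duration
        if rc == 0:
            warnings.warn(f"neuron {nid}: zero control rate, excluded")
            continue
        if direction == "decrease" and rd <= (1.0 - threshold) * rc:
            kept.append(nid)
        elif direction == "increase" and rd >= (1.0 + threshold) * rc:
            kept.append(nid)
    return kept


def inverted_u_test(g_eff_values, entropy_values) -> dict:
    """Quadratic-vs-linear regression test for an inverted-U relationship.

    Fits entropy ~ 1 + g_eff and entropy ~ 1 + g_eff + g_eff^2 by OLS and
    reports both BICs, the 1-df likelihood-ratio p-value, and the sign and
    value of the quadratic coefficient (negative = inverted U).
    """
    import statsmodels.api as sm
    from scipy.stats import chi2

    x = np.asarray(g_eff_values, dtype=float)
    y = np.asarray(entropy_values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 10:
        raise ValueError("need at least 10 points")
    if np.ptp(x) == 0:
        raise ValueError("no spread in g_eff")
    X1 = sm.add_constant(x)
    X2 = np.column_stack([np.ones_like(x), x, x ** 2])
    if np.linalg.matrix_rank(X2) < 3:
        raise ValueError("collinear design matrix")
    lin = sm.OLS(y, X1).fit()
    quad = sm.OLS(y, X2).fit()
    llr = 2.0 * (quad.llf - lin.llf)
    p = float(chi2.sf(llr, df=1))
    b2 = float(quad.params[2])
    # vertex of the fitted parabola (the inverted-U peak when b2 < 0)
    peak = float(-quad.params[1] / (2.0 * b2)) if b2 != 0 else np.nan
    return {
        "quadratic_params": quad.params, "linear_params": lin.params,
        "bic_quadratic": float(quad.bic), "bic_linear": float(lin.bic),
        "llr_pvalue": p, "quadratic_coefficient": b2,
        "peak_g_eff": peak,
        "quadratic_fit": quad, "linear_fit": lin,
    }


def cooks_outliers(x, y, factor: float = 5.0) -> np.ndarray:
    """Indices of points whose Cook's distance exceeds ``factor`` x mean.

    Distances come from the simple linear regression of y on x.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: no spread in x")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    d = res.get_influence().cooks_distance[0]
    return np.where(d > factor * d.mean())[0]


@dataclass
class RunConfig:
    """Configuration of a pipeline run."""

    out_dir: str = "olivenet_run"
    conditions: tuple[str, ...] = ("CBX", "CON", "PIX")
    backend: str = "surrogate"   # 'surrogate' (fast demo) | 'model'
    duration: float = 200.0      # s per condition dataset
    segment_length: float = 50.0
    sync_bin: float = 0.01       # s
    dim_window: float = 50.0     # s
    chaos_window: float = 50.0   # s
    chaos_step: float = 2.0      # s
    seed: int = 0
    g_s: float = 0.1

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if "conditions" in known:
            cfg.conditions = tuple(known["conditions"])
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Generate (or load) condition datasets and run every analysis stage.

    Writes, under ``config.out_dir``: per-condition spike tables, a metrics
    table (rates, synchrony, dimensionality, complexity) and a JSON summary
    including the effective coupling at the printed condition means.  Every
    table carries the config hash and seed.  Returns the summary dict.
    """
    from . import synthetic
    from .chaos import dataset_complexity
    from .inference import effective_coupling
    from .population import dataset_synchrony, dimensionality

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}

    rows = []
    summary = {"stamp": stamp, "conditions": {}}
    for k, cond in enumerate(config.conditions):
        stage = f"dataset:{cond}"
        try:
            ds = synthetic.condition_dataset(
                cond, duration=config.duration, seed=config.seed + k,
                backend=config.backend)
        except Exception as exc:  # pragma: no cover - stage failure surface
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        synthetic.write_spikes(ds, out / f"spikes_{cond}.tsv")
        g_i, g_c = synthetic.CONDITION_MEANS[cond]
        g_eff = effective_coupling(config.g_s, g_c, g_i)
        sync = dataset_synchrony(ds, config.sync_bin)
        d = dimensionality(ds, window=min(config.dim_window, config.duration / 2),
                           step=1.0)
        comp = dataset_complexity(ds, window=config.chaos_window,
                                  step=config.chaos_step)
        row = {
            "condition": cond, "n_neurons": ds.n_neurons,
            "rate": ds.mean_rate(), "synchrony": sync,
            "dimensionality": d, "dimensionality_norm": d / ds.n_neurons,
            "complexity": comp, "g_i": g_i, "g_c": g_c, "g_eff": g_eff,
            **stamp,
        }
        rows.append(row)
        summary["conditions"][cond] = {
            k: v for k, v in row.items() if k not in ("config_hash",)}
    table = pd.DataFrame(rows)
    table.to_csv(out / "metrics.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=2, default=float)
    return summary
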