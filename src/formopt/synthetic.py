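"""Synthetic Box-Behnken datasets with the structure the analysis assumes.

Each of the 15 design runs yields ``n_rep`` replicates drawn from
Normal(truth prediction, per-run SD); the table stores their mean and
sample SD, exactly the summary the real experiment reports.  Defaults
reproduce the study conditions: the truth surfaces are the canonical
refit models, the per-run SDs are the published per-run SDs (a
heteroscedastic pattern of ~0.003–0.04 for permeation rate and
~0.015–0.38 for retention), and n_rep = 6.  The particle-size column is
carried as a constant 20 nm ± 0.5 so the <100 nm data invariant always
holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import FACTOR_COLUMNS, DesignTable, QuadraticModel, study_factors

_Y3_TRUTH = 20.0
_Y3_SD = 0.5


@dataclass
class SyntheticSpec:
    """Ground truth and noise structure for a synthetic design table.

    ``noise_sd`` maps each modelled response to either a scalar SD or a
    per-run SD vector; ``None`` uses the published per-run SDs.
    """

    truth_models: tuple[QuadraticModel, QuadraticModel] | None = None
    noise_sd: dict[str, float | np.ndarray] | None = None
    n_rep: int = 6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_rep < 2:
            raise ValueError("n_rep must be >= 2 to define a sample SD")


def _default_sds(design: DesignTable, response: str) -> np.ndarray:
    sds = design.response_sds(response)
    if sds is None:
        raise ValueError(f"no SD column for {response} in template design")
    return sds


def generate_bbd_responses(
    spec: SyntheticSpec, design: DesignTable | None = None
) -> DesignTable:
    """Draw a synthetic replicate of the Box-Behnken experiment.

    Uses the factor settings (and, by default, the per-run SD pattern) of
    ``design`` — the packaged table when omitted — and replaces all
    response columns with simulated means and sample SDs.
    """
    from .fixtures import canonical_models, load_table1

    if design is None:
        design = load_table1()
    truth = spec.truth_models or canonical_models()
    rng = np.random.default_rng(spec.seed)
    x = design.factor_settings(x3_as_fraction=True)
    out = design.data.loc[:, ["run"] if "run" in design.data.columns else []].copy()
    for col in FACTOR_COLUMNS:
        out[col] = design.data[col].to_numpy()
    for response, model in zip(("Y1", "Y2"), truth):
        mu = model.predict(x)
        if spec.noise_sd is not None and response in spec.noise_sd:
            sd = np.broadcast_to(np.asarray(spec.noise_sd[response], float), mu.shape)
        else:
            sd = _default_sds(design, response)
        if np.any(sd < 0):
            raise ValueError(f"negative noise SD for {response}")
        reps = rng.normal(mu[:, None], sd[:, None], size=(len(mu), spec.n_rep))
        out[f"{response}_mean"] = reps.mean(axis=1)
        out[f"{response}_sd"] = reps.std(axis=1, ddof=1)
    reps3 = rng.normal(_Y3_TRUTH, _Y3_SD, size=(len(x), spec.n_rep))
    out["Y3_mean"] = reps3.mean(axis=1)
    out["Y3_sd"] = reps3.std(axis=1, ddof=1)
    return DesignTable(data=out, n_rep=spec.n_rep, factors=study_factors())
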