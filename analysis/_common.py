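"""Shared loading for the analysis drivers: panel + fitted models from disk."""

from pathlib import Path

import yaml

from flsim import read_panel
from flsim.models import (CovariateUpdateModel, FLTransitionModel,
                          ImputationModel, impute_missing_fl)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def load_panel_and_models(seed: int):
    panel = read_panel(RESULTS / "panel.csv")
    with open(RESULTS / "models.yaml") as fh:
        payload = yaml.safe_load(fh)
    fl_model = FLTransitionModel(**payload["fl_transition"])
    updates = {k: CovariateUpdateModel(**v)
               for k, v in payload["covariate_updates"].items()}
    if panel.df["fl"].isna().any():
        imp = payload["imputation"]
        model = ImputationModel(terms=tuple(imp["terms"]),
                                intercept=imp["intercept"],
                                coefs=tuple(imp["coefs"]))
        panel = impute_missing_fl(panel, model, seed=seed)
    return panel, fl_model, updates
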