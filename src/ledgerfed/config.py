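"""Structured YAML configuration for the CLI drivers.

Example:

.. code-block:: yaml

    cohort:
      n_patients: [300, 300, 120]   # one entry per site
      prevalence: 0.12
      signal: 1.0
      seed: 7
    consortium:
      trainer_ids: [hospital_a, hospital_b]
      validator_id: coordinator
      rounds: 30
      seed: 7
    governance:
      lam: 1.0
      mu: 0.5
    training:
      lr: 5.0e-4
      max_epochs: 120
"""

from __future__ import annotations

import yaml

from ledgerfed import cohort as ch
from ledgerfed import governance as gov
from ledgerfed import risk_model as rm
from ledgerfed.consortium import ConsortiumConfig


def load_config(path: str) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def build_cohort(cfg: dict) -> ch.RawCohort:
    c = cfg.get("cohort", {})
    signal = float(c.get("signal", 1.0))
    variables = ch.default_variables(signal=signal)
    n_patients = c.get("n_patients", [300, 300])
    seed = int(c.get("seed", 0))
    prevalence = float(c.get("prevalence", 0.12))
    if len(n_patients) == 1:
        sites = [ch.single_site(int(n_patients[0]), prevalence=prevalence)]
    else:
        sites = ch.multi_site(tuple(int(n) for n in n_patients), seed=seed,
                              base_prevalence=prevalence, variables=variables)
    return ch.generate_cohort(variables, sites, horizon_hours=int(c.get("horizon_hours", 48)),
                              seed=seed, label_slope=float(c.get("label_slope", 3.0)))


def build_consortium_config(cfg: dict) -> ConsortiumConfig:
    c = cfg.get("consortium", {})
    return ConsortiumConfig(
        trainer_ids=tuple(c.get("trainer_ids", ["hospital_a", "hospital_b"])),
        validator_id=c.get("validator_id", "coordinator"),
        rounds=int(c.get("rounds", 30)),
        local_epochs=int(c.get("local_epochs", 1)),
        aggregation=c.get("aggregation", "reputation_weighted"),
        disable_governance=bool(c.get("disable_governance", False)),
        disable_incentives=bool(c.get("disable_incentives", False)),
        disable_privacy=bool(c.get("disable_privacy", False)),
        seed=int(c.get("seed", 0)),
    )


def build_governance_config(cfg: dict) -> gov.GovernanceConfig:
    g = dict(cfg.get("governance", {}))
    return gov.GovernanceConfig(**g)


def build_train_config(cfg: dict, seed: int = 0) -> rm.TrainConfig:
    t = dict(cfg.get("training", {}))
    t.setdefault("seed", seed)
    return rm.TrainConfig(**t)
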