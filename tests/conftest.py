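"""Shared fixtures: synthetic panels and (expensive) model fits reused across
test modules.  All seeds are fixed constants so the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rtscale import (LocationScaleSpec, PanelConfig, extract_person_components,
                     fit_expanded_location_scale, generate_panel,
                     log_transform)

LN10 = float(np.log(10.0))


def true_ti_table(panel):
    """TI table built from the generator's true item time intensities."""
    ti = panel.item_truth.copy()
    ti["ti_centered"] = ti["ti_log"] - LN10
    ti["ti_se"] = 0.0
    return ti


@pytest.fixture(scope="session")
def small_panel():
    """120 persons x 6 surveys x 10 items with 1% contamination."""
    cfg = PanelConfig(n_persons=120, n_surveys=6, items_per_survey=10,
                      contamination_rate=0.01, seed=11)
    return generate_panel(cfg)


@pytest.fixture(scope="session")
def recovery_panel():
    """The parameter-recovery condition: 300 persons x 150 items,
    gamma00=2.33, gamma10=1, tau=diag(.16,.04,.25)."""
    cfg = PanelConfig(n_persons=300, n_surveys=10, items_per_survey=15,
                      seed=42)
    return generate_panel(cfg)


@pytest.fixture(scope="session")
def recovery_fit(recovery_panel):
    """Expanded location-scale fit of the recovery panel against true TIs."""
    clean = log_transform(recovery_panel.rt_records)
    spec = LocationScaleSpec(chains=2, iterations=3000, burn_in=1000, seed=44)
    return fit_expanded_location_scale(clean, true_ti_table(recovery_panel),
                                       spec)


@pytest.fixture(scope="session")
def recovery_components(recovery_fit, recovery_panel):
    comp = extract_person_components(recovery_fit)
    return comp.merge(recovery_panel.person_truth, on="person_id")


@pytest.fixture(scope="session")
def wide_panel():
    """Survey-like regime: thousands of respondents per item, 1%
    contamination — the setting where per-item percentile trimming can
    isolate planted outliers."""
    cfg = PanelConfig(n_persons=10000, n_surveys=1, items_per_survey=30,
                      contamination_rate=0.01, seed=0)
    return generate_panel(cfg)


@pytest.fixture(scope="session")
def tau_zero_panel():
    """Degenerate generator: no person heterogeneity at all."""
    cfg = PanelConfig(n_persons=100, n_surveys=5, items_per_survey=20,
                      tau=np.zeros((3, 3)), seed=13)
    return generate_panel(cfg)


def make_clean_records(panel):
    """Log-transform without trimming (data straight from the model)."""
    return log_transform(panel.rt_records)


@pytest.fixture(scope="session")
def tau_zero_fits(tau_zero_panel):
    """Plain and expanded fits of the homogeneous (tau = 0) panel."""
    from rtscale import fit_location_scale

    clean = log_transform(tau_zero_panel.rt_records)
    plain = fit_location_scale(
        clean, LocationScaleSpec(chains=2, iterations=1500, burn_in=600,
                                 seed=3))
    expanded = fit_expanded_location_scale(
        clean, true_ti_table(tau_zero_panel),
        LocationScaleSpec(chains=2, iterations=1500, burn_in=600, seed=4))
    return {"plain": plain, "expanded": expanded}


@pytest.fixture(scope="session")
def nested_limit_fits():
    """Generator with no TI effect (gamma10=0, tau11=0): the expanded model
    nests the plain one, so both fits should agree on gamma00 and omega."""
    from rtscale import fit_location_scale

    cfg = PanelConfig(n_persons=80, n_surveys=3, items_per_survey=15,
                      tau=np.diag([0.16, 0.0, 0.2]), gamma10=0.0, omega=-1.6,
                      marginal_log_rt_sd=0.79, seed=29)
    panel = generate_panel(cfg)
    clean = log_transform(panel.rt_records)
    expanded = fit_expanded_location_scale(
        clean, true_ti_table(panel),
        LocationScaleSpec(chains=2, iterations=3000, burn_in=1200, seed=6))
    plain = fit_location_scale(
        clean, LocationScaleSpec(chains=2, iterations=3000, burn_in=1200,
                                 seed=7))
    return {"plain": plain, "expanded": expanded, "panel": panel}


@pytest.fixture(scope="session")
def ls_oracle_toy():
    """Small plain location-scale data set plus its MML (quadrature) fit and
    a long MCMC fit, for posterior-mean vs maximum-likelihood comparison."""
    from rtscale import fit_location_scale, fit_mml

    cfg = PanelConfig(n_persons=20, n_surveys=1, items_per_survey=25,
                      tau=np.diag([0.16, 0.0, 0.2]), gamma10=0.0, ti_sd=0.3,
                      omega=-1.6, marginal_log_rt_sd=0.79, seed=5)
    panel = generate_panel(cfg)
    rec = log_transform(panel.rt_records)
    mml = fit_mml(rec, expanded=False)
    mcmc = fit_location_scale(
        rec, LocationScaleSpec(chains=2, iterations=12000, burn_in=4000,
                               seed=2))
    return {"records": rec, "mml": mml, "mcmc": mcmc, "panel": panel}


@pytest.fixture(scope="session")
def xls_oracle_toy():
    """Expanded-model analogue of ``ls_oracle_toy`` (3 random-effect dims)."""
    from rtscale import fit_mml

    cfg = PanelConfig(n_persons=20, n_surveys=2, items_per_survey=15,
                      tau=np.diag([0.16, 0.04, 0.2]), seed=31)
    panel = generate_panel(cfg)
    rec = log_transform(panel.rt_records)
    ti = true_ti_table(panel)
    mml = fit_mml(rec, expanded=True, ti=ti, nodes=9)
    mcmc = fit_expanded_location_scale(
        rec, ti, LocationScaleSpec(chains=2, iterations=12000, burn_in=4000,
                                   seed=8))
    return {"records": rec, "ti": ti, "mml": mml, "mcmc": mcmc, "panel": panel}
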