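"""Calibration studies: repeated-simulation checks of the pipeline's
statistical behaviour against the generator's planted truth.

Each study runs the relevant pipeline machinery over freshly generated
cohorts at the stated conditions and reports recovery/error rates.  Seeds
are derived from a single base seed so the studies are reproducible.
"""

from __future__ import annotations

import numpy as np

from .pipeline import run_pipeline
from .splice import compute_psi, event_group_test, fdr_adjust, SpliceEvent
from .survival import fit_ph
from .synth import (SimConfig, generate_cohort, simulate_psi_events,
                    simulate_survival_cohort)


def _seeds(base_seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(base_seed).generate_state(n) % (2**31)]


def _surv_frame(df):
    return df.rename(columns={"time": "os_time", "event": "os_event"})


def null_fdr_study(base_seed: int = 0, n_seeds: int = 20,
                   n_events: int = 2000, coverage: int = 100,
                   reps: int = 3) -> list[float]:
    """Fraction of planted-null events called at q < 0.05, per seed.

    With BH adjustment over each seed's batch, the expected fraction of
    nulls crossing q < 0.05 is bounded by the FDR level itself.
    """
    fractions = []
    for seed in _seeds(base_seed, n_seeds):
        rng = np.random.default_rng(seed)
        sims = simulate_psi_events(n_events, 0.0, coverage, reps, rng)
        dummy = SpliceEvent("e", "g", "chr1", "+")
        pvals = [event_group_test(dummy, ca, cb).p for ca, cb, _ in sims]
        q = np.asarray(fdr_adjust(pvals))
        fractions.append(float((q < 0.05).mean()))
    return fractions


def dpsi_recovery_study(base_seed: int = 0, n_seeds: int = 20,
                        n_events: int = 200, dpsi: float = 0.3,
                        coverage: int = 100, reps: int = 3) -> dict:
    """Per-event dPSI estimation error at planted dPSI.

    Returns the fraction of events whose estimate lies within +-0.05 of
    the planted value, the mean absolute error, and the grand-mean
    estimate (clipping at PSI = 1 is avoided by the control-PSI range).
    """
    within, errors, estimates = [], [], []
    for seed in _seeds(base_seed, n_seeds):
        rng = np.random.default_rng(seed)
        for ca, cb, _ in simulate_psi_events(n_events, dpsi, coverage,
                                             reps, rng):
            pa = np.mean([compute_psi(i, s) for i, s in ca])
            pb = np.mean([compute_psi(i, s) for i, s in cb])
            est = (pb - pa) / 100.0
            estimates.append(est)
            errors.append(abs(est - dpsi))
            within.append(abs(est - dpsi) <= 0.05)
    return {"fraction_within_0.05": float(np.mean(within)),
            "mean_abs_error": float(np.mean(errors)),
            "mean_estimate": float(np.mean(estimates)),
            "n_events": len(estimates)}


def hazard_recovery_study(base_seed: int = 0, n_seeds: int = 100,
                          n: int = 400, true_hr: float = 2.0) -> dict:
    """Two-group Cox recovery of a planted hazard ratio."""
    estimates = []
    for seed in _seeds(base_seed, n_seeds):
        rng = np.random.default_rng(seed)
        df = _surv_frame(simulate_survival_cohort(n, np.log(true_hr), rng,
                                                  two_group=True))
        estimates.append(fit_ph(df, ["x"], "os")[0].hr)
    estimates = np.asarray(estimates)
    return {"n_in_band": int(((estimates >= 1.6) & (estimates <= 2.5)).sum()),
            "n_seeds": n_seeds,
            "mean_hr": float(estimates.mean())}


def null_ci_coverage_study(base_seed: int = 0, n_seeds: int = 200,
                           n: int = 400) -> dict:
    """95% Wald CI coverage of HR = 1 for a covariate with no effect."""
    covered = 0
    for seed in _seeds(base_seed, n_seeds):
        rng = np.random.default_rng(seed)
        df = _surv_frame(simulate_survival_cohort(n, 0.0, rng))
        fit = fit_ph(df, ["x"], "os")[0]
        covered += fit.ci_low <= 1.0 <= fit.ci_high
    return {"coverage": covered / n_seeds, "n_seeds": n_seeds}


def driver_recovery_study(base_seed: int = 0, n_seeds: int = 50,
                          **config_kwargs) -> dict:
    """Full-pipeline driver recovery: how often the planted driver is the
    unique gene passing every filter."""
    unique, stable_any = 0, 0
    for seed in _seeds(base_seed, n_seeds):
        bundle, ledger = generate_cohort(SimConfig(seed=seed,
                                                   **config_kwargs))
        res = run_pipeline(bundle, set(ledger.splicing_factors),
                           set(ledger.immune_set),
                           set(ledger.malignancy_set))
        unique += res.stable_genes == {ledger.planted_driver}
        stable_any += ledger.planted_driver in res.stable_genes
    return {"n_unique_driver": unique, "n_driver_stable": stable_any,
            "n_seeds": n_seeds}
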