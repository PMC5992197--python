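"""End-to-end orchestration: behaviour -> recall -> change point ->
trial-ITI comparison -> decoding, for one session or a cohort.

A single master seed is split deterministically across stages, so a run
is reproducible from its manifest alone.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import behaviour, changepoint, decoding, recall, trial_iti
from .session_model import Session

log = logging.getLogger("mazerecall")

SIGMA_SWEEP_BOUNDS = (0.02, 0.24)


@dataclass(frozen=True)
class RunConfig:
    sigma: float = 0.1
    dt: float = 0.01
    n_shuffles_recall: int = 1000
    n_shuffles_decoder: int = 50
    n_perm: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    groupings: tuple = ("prior_outcome", "prior_arm", "prior_cue", "next_outcome")
    decoders: tuple = ("logistic",)
    features: tuple = decoding.FEATURES
    pair_counting: str = "offdiag"
    min_before: int = 3
    min_after: int = 5

    def __post_init__(self):
        lo, hi = SIGMA_SWEEP_BOUNDS
        if not lo <= self.sigma <= hi:
            raise ValueError(f"sigma must lie in [{lo}, {hi}] s")
        for name in ("dt", "n_shuffles_recall", "n_shuffles_decoder", "n_perm",
                     "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dt > self.sigma / 5:
            raise ValueError("dt must be <= sigma/5")
        unknown = set(self.groupings) - set(recall.GROUPINGS)
        if unknown:
            raise ValueError(f"unknown groupings {unknown}")
        unknown = set(self.decoders) - set(decoding.DECODERS)
        if unknown:
            raise ValueError(f"unknown decoders {unknown}")

    def manifest(self) -> dict:
        import scipy
        import sklearn

        from . import __version__

        return {
            "config": asdict(self),
            "versions": {
                "mazerecall": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "scikit-learn": sklearn.__version__,
            },
        }


def _stage(report, name, fn):
    t0 = time.perf_counter()
    try:
        out = fn()
        log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return out
    except Exception as exc:  # downstream stages degrade gracefully
        log.warning("stage %s failed: %s", name, exc)
        report.setdefault("errors", {})[name] = str(exc)
        return None


def run_session(session: Session, config: RunConfig, session_id="session") -> dict:
    """Run the full analysis on one session; returns a JSON-ready report."""
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    seed_recall, seed_trial_iti, seed_decode = (
        int(s.generate_state(1)[0] % (2**31)) for s in seeds
    )
    report: dict = {"session_id": str(session_id), "n_trials": session.n_trials,
                    "n_neurons": session.n_neurons, "rule_type": session.rule_type}

    cls = _stage(
        report, "behaviour", lambda: behaviour.classify_session(session.trials)
    )
    if cls is not None:
        report["behaviour"] = {
            "label": cls.label,
            "learning_trial": cls.learning_trial,
            "steepest_trial": cls.steepest_trial,
            "r_before": cls.fit.r_before if cls.fit else None,
            "r_after": cls.fit.r_after if cls.fit else None,
        }

    res = _stage(
        report,
        "recall",
        lambda: recall.recall_analysis(
            session, config.sigma, config.dt, config.n_shuffles_recall, seed_recall
        ),
    )
    if res is not None:
        report["recall"] = {"core_size": int(res.core_neurons.size), "groupings": {}}
        for grouping in config.groupings:
            cmp_ = _stage(
                report,
                f"recall[{grouping}]",
                lambda g=grouping: recall.compare_groups(
                    res, session, g, config.pair_counting
                ),
            )
            if cmp_ is not None:
                report["recall"]["groupings"][grouping] = {
                    "delta": cmp_.delta,
                    "mean_block1": cmp_.mean_block1,
                    "mean_block2": cmp_.mean_block2,
                    "ks_stat": cmp_.ks_stat,
                    "ks_p": cmp_.ks_p,
                    "blocks": [cmp_.block1, cmp_.block2],
                }

        oo = _stage(
            report,
            "changepoint",
            lambda: changepoint.detect_onset_offset(
                res.residual, config.min_before, config.min_after, config.alpha
            ),
        )
        if oo is not None:
            report["changepoint"] = {
                "onset_trial": oo.onset_trial,
                "offset_trial": oo.offset_trial,
                "onset_stat": oo.onset_stat,
                "offset_stat": oo.offset_stat,
                "onset_p": oo.onset_p,
                "offset_p": oo.offset_p,
            }

    ti = _stage(
        report,
        "trial_iti",
        lambda: trial_iti.trial_iti_similarity(
            session, config.sigma, config.dt, seed=seed_trial_iti
        ),
    )
    if ti is not None:
        report["trial_iti"] = {
            "mean_delta_within": float(ti.delta_within.mean()),
            "sign_test_p": ti.sign_test_p,
            "core_size": int(ti.core_neurons.size),
        }

    core = recall.core_population(session)
    if core.size >= 1:
        rates = _stage(report, "rate_vectors",
                       lambda: decoding.rate_vectors(session, core))
        if rates is not None:
            report["decoding"] = {}
            for feature in config.features:
                for dec in config.decoders:
                    dr = _stage(
                        report,
                        f"decode[{feature},{dec}]",
                        lambda f=feature, d=dec: decoding.decode_session(
                            session, core, f, d, config.n_shuffles_decoder,
                            seed_decode, rates=rates
                        ),
                    )
                    if dr is not None:
                        report["decoding"][f"{feature}:{dec}"] = {
                            str(p): {
                                "accuracy": sd.accuracy,
                                "chance_mean": float(sd.chance.mean()),
                                "relative": sd.relative,
                                "n_examples": sd.n_examples,
                            }
                            for p, sd in dr.sections.items()
                        }
    report["manifest"] = config.manifest()
    return report


def run_cohort(sessions, config: RunConfig) -> dict:
    """Run many sessions and the cross-session permutation test.

    `sessions` is a sequence of Session or of (id, Session) pairs. The
    permutation test asks how likely it is that a random subset the size
    of the learning-labelled group consists entirely of sessions with
    positive Delta_R(prior_outcome).
    """
    sessions = list(sessions)
    if not sessions:
        raise ValueError("empty cohort")
    if not isinstance(sessions[0], tuple):
        sessions = [(f"session{i:03d}", s) for i, s in enumerate(sessions, 1)]

    reports = {}
    deltas, labels = [], []
    for sid, sess in sessions:
        rep = run_session(sess, config, session_id=sid)
        reports[sid] = rep
        g = rep.get("recall", {}).get("groupings", {}).get("prior_outcome")
        deltas.append(g["delta"] if g else np.nan)
        labels.append(rep.get("behaviour", {}).get("label"))

    deltas = np.asarray(deltas, dtype=float)
    learning_ids = [i for i, l in enumerate(labels) if l == "learning"]
    perm_p = None
    if learning_ids and np.isfinite(deltas).all():
        perm_p = recall.session_permutation_test(
            deltas,
            learning_ids,
            config.n_perm,
            np.random.default_rng(config.seed),
        )
    return {
        "sessions": reports,
        "delta_prior_outcome": deltas.tolist(),
        "labels": labels,
        "n_learning": len(learning_ids),
        "permutation_p": perm_p,
        "manifest": config.manifest(),
    }
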