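"""End-to-end orchestration: recode -> fit sweep -> diagnostics -> three-step.

A run consumes the wide survey CSV plus the long service-record CSVs,
recodes them, sweeps latent class models over a class range, writes
the model-comparison table and separation diagnostics, and — for the
analyst-chosen class count — produces the class-profile table, the
BCH-weighted covariate association table and the BCH (optionally
IP-weighted) distal service-use tables.  Every artifact is a tidy CSV;
a manifest (seeds, configuration, output hashes, package version)
makes the run reproducible bit for bit.

Class-count selection is deliberately not automatic: the sweep report
restates the criteria (AIC/BIC, entropy, class sizes, stability,
AvePP) and the analyst chooses.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .lca import FitResult, LatentClassModel
from .recode import INDICATORS, build_indicator_matrix, recode_outcome_table
from .selection import avepp_matrix, fit_sweep, selection_report
from .three_step import (
    bch_distal,
    bch_multinomial_regression,
    bch_weights,
    classification_matrix,
    ip_weights,
    modal_assignment,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline", "class_profile_table", "name_suggestions"]

OUTCOME_COLUMNS = [
    "gp_category",
    "specialist_category",
    "medication_category",
    "any_admission",
    "same_day_admission",
    "overnight_admission",
]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run (loadable from YAML/JSON)."""

    survey: str
    covariates: str
    visits: str
    dispensings: str
    admissions: str
    outdir: str
    c_min: int = 1
    c_max: int = 6
    chosen_c: int | str = "ask"
    n_starts: int = 100
    seed: int = 0
    reference: int | str = "largest"
    n_bootstrap: int = 500
    ip_weighting: bool = True
    tol: float = 1e-6
    max_iter: int = 5000

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def validate(self) -> None:
        for name in ("survey", "covariates", "visits", "dispensings", "admissions"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} input {p!r} does not exist")
        if self.c_min < 1 or self.c_max < self.c_min:
            raise ValueError("need 1 <= c_min <= c_max")


def class_profile_table(fit: FitResult, data) -> pd.DataFrame:
    """Per indicator x response level: marginal vs class-specific percents.

    Class percents come from the fitted item-response probabilities;
    posterior-weighted empirical percents are reported alongside.  The
    marginal column is the prevalence-weighted mixture of the class
    profiles, and each cell is flagged higher / lower / neutral
    relative to it — the comparison used to characterise and name the
    classes.
    """
    X = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) else np.asarray(data, float)
    names = list(data.columns) if isinstance(data, pd.DataFrame) else [
        f"item_{j}" for j in range(X.shape[1])
    ]
    params = fit.params
    post = fit.posteriors
    C, J = params.C, params.J
    level_names = {0: "never/rarely", 1: "sometimes", 2: "often"}
    rows = []
    marginal = np.einsum("c,cjk->jk", params.gamma, params.rho)
    for j in range(J):
        obs = ~np.isnan(X[:, j])
        for k in range(params.K[j]):
            m_pct = 100.0 * marginal[j, k]
            denom = post[obs].sum(axis=0)
            emp = 100.0 * (post[obs] * (X[obs, j] == k)[:, None]).sum(axis=0) / denom
            for c in range(C):
                cp = 100.0 * params.rho[c, j, k]
                diff = cp - m_pct
                flag = "higher" if diff > 1e-9 else ("lower" if diff < -1e-9 else "neutral")
                rows.append(
                    {
                        "indicator": names[j],
                        "level": level_names.get(k, str(k)),
                        "marginal_pct": m_pct,
                        "class": c,
                        "class_pct": cp,
                        "class_pct_empirical": emp[c],
                        "flag": flag,
                    }
                )
    return pd.DataFrame(rows)


def name_suggestions(profile: pd.DataFrame) -> pd.DataFrame:
    """Deterministic per-class descriptor summary from the profile flags.

    Lists each class's indicators flagged higher / lower than marginal
    at the 'sometimes' and 'often' levels.  Naming the classes remains
    the analyst's act; this only organises the evidence.
    """
    rows = []
    for c in sorted(profile["class"].unique()):
        sub = profile[profile["class"] == c]
        entry = {"class": c}
        for level in ("sometimes", "often"):
            lv = sub[sub["level"] == level]
            entry[f"higher_{level}"] = ", ".join(lv.loc[lv["flag"] == "higher", "indicator"])
            entry[f"lower_{level}"] = ", ".join(lv.loc[lv["flag"] == "lower", "indicator"])
        freq = sub[sub["level"].isin(["sometimes", "often"])]
        if (freq["flag"] == "lower").all():
            entry["summary"] = "below-marginal on all indicators"
        elif (freq["flag"] == "higher").all():
            entry["summary"] = "above-marginal on all indicators"
        elif (freq["flag"] == "neutral").all():
            entry["summary"] = "at the marginal profile"
        else:
            n_hi = int((freq["flag"] == "higher").sum())
            entry["summary"] = f"mixed profile ({n_hi} elevated cells)"
        rows.append(entry)
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns {artifact name: path} for the bundle.

    Any stage failure raises :class:`PipelineStageError` naming the
    stage; artifacts written before the failure are left in place.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    timings: dict[str, float] = {}

    def _stage(name):
        logger.info("stage %s", name)
        timings[name] = time.time()

    def _done(name):
        timings[name] = round(time.time() - timings[name], 3)

    def _write(name, df: pd.DataFrame, index=False):
        path = outdir / name
        df.to_csv(path, index=index)
        artifacts[name] = path

    try:
        _stage("recode")
        survey = pd.read_csv(config.survey)
        covariates = pd.read_csv(config.covariates)
        visits = pd.read_csv(config.visits)
        dispensings = pd.read_csv(config.dispensings)
        admissions = pd.read_csv(config.admissions)
        indicators = build_indicator_matrix(survey)
        survey_dates = pd.Series(
            pd.to_datetime(survey.set_index("participant_id")["survey_return_date"]).dt.date,
            name="survey_return_date",
        ).loc[indicators.index]
        outcomes = recode_outcome_table(survey_dates, visits, dispensings, admissions)
        covariates = covariates.set_index("participant_id").loc[indicators.index]
        _write("indicators.csv", indicators, index=True)
        _write("outcomes.csv", outcomes, index=True)
        _done("recode")
    except Exception as exc:
        raise PipelineStageError("recode", exc) from exc

    try:
        _stage("sweep")
        sweep, fits = fit_sweep(
            indicators,
            C_range=range(config.c_min, config.c_max + 1),
            n_starts=config.n_starts,
            seed=config.seed,
            tol=config.tol,
            max_iter=config.max_iter,
        )
        _write("sweep.csv", sweep)
        _done("sweep")
    except Exception as exc:
        raise PipelineStageError("sweep", exc) from exc

    try:
        _stage("select")
        if config.chosen_c == "ask":
            raise ValueError(
                "chosen_c is 'ask': inspect sweep.csv / selection_report.txt and re-run "
                "with an explicit class count"
            )
        C = int(config.chosen_c)
        model = fits[C]
        fit = model.result_
        avepp = avepp_matrix(fit.posteriors) if C >= 2 else np.ones((1, 1))
        labels = [f"class_{c}" for c in range(C)]
        _write("avepp.csv", pd.DataFrame(avepp, index=labels, columns=labels), index=True)
        report = selection_report(sweep, avepp if C >= 2 else None)
        (outdir / "selection_report.txt").write_text(report + "\n")
        artifacts["selection_report.txt"] = outdir / "selection_report.txt"
        profile = class_profile_table(fit, indicators)
        _write("profile.csv", profile)
        _write("class_descriptors.csv", name_suggestions(profile))
        _done("select")
    except Exception as exc:
        raise PipelineStageError("select", exc) from exc

    try:
        _stage("three_step")
        post = fit.posteriors
        modal = modal_assignment(post)
        D = classification_matrix(post, modal)
        u = bch_weights(D, modal)
        ss = np.random.SeedSequence([config.seed, 3])
        s_assoc, s_distal = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
        assoc, cov_model = bch_multinomial_regression(
            covariates,
            u,
            reference=config.reference,
            n_bootstrap=config.n_bootstrap,
            seed=s_assoc,
        )
        _write("associations.csv", assoc)
        ipw = ip_weights(cov_model, covariates, u) if config.ip_weighting else None
        distal_rows = []
        for col in OUTCOME_COLUMNS:
            outcome = outcomes[col].astype(str)
            tab = bch_distal(u, outcome, n_bootstrap=config.n_bootstrap, seed=s_distal)
            tab.insert(0, "outcome", col)
            tab["weighting"] = "BCH"
            distal_rows.append(tab)
            if ipw is not None:
                tab2 = bch_distal(
                    u, outcome, extra_weights=ipw.weights,
                    n_bootstrap=config.n_bootstrap, seed=s_distal,
                )
                tab2.insert(0, "outcome", col)
                tab2["weighting"] = "BCH+IP"
                distal_rows.append(tab2)
        _write("distal.csv", pd.concat(distal_rows, ignore_index=True))
        if ipw is not None:
            bal = ipw.smd_before.rename(columns={"smd": "smd_bch"}).merge(
                ipw.smd_after.rename(columns={"smd": "smd_bch_ip"}), on=["term", "class"]
            )
            _write("balance.csv", bal)
        _done("three_step")
    except Exception as exc:
        raise PipelineStageError("three_step", exc) from exc

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "n_individuals": int(len(indicators)),
        "chosen_c": int(config.chosen_c),
        "timings_s": timings,
        "artifact_hashes": {name: _sha256(path) for name, path in artifacts.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    artifacts["manifest.json"] = outdir / "manifest.json"
    return {k: str(v) for k, v in artifacts.items()}
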