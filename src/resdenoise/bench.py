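"""Mutation-assay benchmark curation and rank-correlation evaluation.

Assays group mutant records of one protein measured under one
experimental condition (pH, optionally temperature), following the
melting-temperature (ΔTm) and folding-free-energy (ΔΔG) thermostability
benchmark conventions: ΔTm-style assays are named ``UniProtID-pH`` and
keep single-site substitutions only; ΔΔG-style assays are named
``PDBID-pH-temperature`` and drop records whose stated wild-type letter
cannot be aligned with the sequence extracted from the structure.  Groups
with fewer than 10 surviving mutants are discarded so each correlation is
meaningful.

Evaluation uses Spearman's rank correlation per assay; the summary
resamples 50% of the assays for 10 independent runs and reports the mean
and standard deviation of the run-level averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import ConfigError, ValidationError
from .scoring import parse_mutant


@dataclass
class Assay:
    """One protein x condition group of (mutant string, experimental score)."""

    name: str
    protein_id: str
    records: list
    ph: float | None = None
    temperature_C: float | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError(f"assay {self.name!r} has no records")
        muts = [m for m, _ in self.records]
        if len(set(muts)) != len(muts):
            raise ValidationError(f"duplicate mutant strings in assay {self.name!r}")

    @property
    def mutants(self) -> list:
        return [m for m, _ in self.records]

    @property
    def scores(self) -> np.ndarray:
        return np.asarray([s for _, s in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["mutant", "score"])


@dataclass
class EvalResult:
    """Per-assay Spearman correlations with macro and bootstrap summaries."""

    per_assay_rho: dict
    macro_mean: float
    bootstrap_mean: float
    bootstrap_std: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.per_assay_rho.items()), columns=["assay", "rho"]
        )


def assay_name(protein_id: str, ph, temperature_C=None) -> str:
    """Render the conventional assay name: pH with one decimal, integer °C."""
    name = f"{protein_id}"
    if ph is not None:
        name += f"-{float(ph):.1f}"
    if temperature_C is not None:
        name += f"-{int(round(float(temperature_C)))}"
    return name


def _is_multisite(mutant: str) -> bool:
    return ":" in mutant


def _aligns(mutant: str, sequence: str) -> bool:
    try:
        parse_mutant(mutant, sequence)
        return True
    except Exception:
        return False


def curate_assays(
    raw_table: pd.DataFrame,
    mode: str,
    reference_sequences: dict | None = None,
    min_mutants: int = 10,
):
    """Group and filter a raw mutant table into named assays.

    Rows need columns ``protein_id, mutant, score, ph`` (plus
    ``temperature`` in ``ddg`` mode).  ``dtm`` mode removes multi-site
    records; ``ddg`` mode removes records that cannot be aligned with the
    reference sequence of their protein; both then drop groups with fewer
    than ``min_mutants`` surviving records and de-duplicate mutant strings
    (first occurrence kept).
    """
    if mode not in {"dtm", "ddg"}:
        raise ConfigError("mode must be 'dtm' or 'ddg'")
    required = {"protein_id", "mutant", "score", "ph"}
    if mode == "ddg":
        required |= {"temperature"}
    missing = required - set(raw_table.columns)
    if missing:
        raise ValidationError(f"raw table missing columns: {sorted(missing)}")

    group_cols = ["protein_id", "ph"] + (["temperature"] if mode == "ddg" else [])
    assays = []
    for key, group in raw_table.groupby(group_cols, dropna=False, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        protein_id, ph = str(key[0]), key[1]
        temperature = key[2] if mode == "ddg" else None
        group = group.drop_duplicates(subset="mutant", keep="first")
        if mode == "dtm":
            group = group[~group["mutant"].map(_is_multisite)]
        else:
            ref = (reference_sequences or {}).get(protein_id)
            if ref is None:
                continue
            group = group[group["mutant"].map(lambda m: _aligns(m, ref))]
        if len(group) < min_mutants:
            continue
        assays.append(
            Assay(
                name=assay_name(protein_id, ph, temperature),
                protein_id=protein_id,
                records=list(zip(group["mutant"], group["score"].astype(float))),
                ph=None if pd.isna(ph) else float(ph),
                temperature_C=None if temperature is None or pd.isna(temperature) else float(temperature),
            )
        )
    return assays


def spearman_rho(predicted, experimental) -> float:
    """Spearman's rank correlation (average ranks for ties)."""
    predicted = np.asarray(predicted, dtype=float)
    experimental = np.asarray(experimental, dtype=float)
    if predicted.shape != experimental.shape or predicted.size < 2:
        raise ValidationError("need two equal-length vectors with >= 2 entries")
    if np.ptp(predicted) == 0 or np.ptp(experimental) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    rho = spearmanr(predicted, experimental).statistic
    return float(rho)


def evaluate_assays(
    assays,
    scorer,
    frac: float = 0.5,
    runs: int = 10,
    seed: int = 0,
) -> EvalResult:
    """Score every assay with ``scorer(assay) -> predictions`` and summarize."""
    per_assay = {a.name: spearman_rho(scorer(a), a.scores) for a in assays}
    macro = float(np.mean(list(per_assay.values())))
    boot_mean, boot_std = bootstrap_summary(per_assay, frac=frac, runs=runs, seed=seed)
    return EvalResult(
        per_assay_rho=per_assay,
        macro_mean=macro,
        bootstrap_mean=boot_mean,
        bootstrap_std=boot_std,
    )


def bootstrap_summary(
    per_assay_rho: dict,
    frac: float = 0.5,
    runs: int = 10,
    seed: int = 0,
    replace: bool = False,
) -> tuple:
    """Assay-level resampling summary of correlation scores.

    Per run, sample ``ceil(frac * N)`` assays (without replacement by
    default) and average their correlations; return the mean and standard
    deviation of the run averages.
    """
    if not 0.0 < frac <= 1.0:
        raise ConfigError("frac must lie in (0, 1]")
    names = sorted(per_assay_rho)
    if len(names) < 2:
        raise ValidationError("need at least 2 assays to bootstrap")
    rhos = np.asarray([per_assay_rho[n] for n in names])
    rng = np.random.default_rng(seed)
    m = int(np.ceil(frac * len(names)))
    means = [
        rhos[rng.choice(len(names), size=m, replace=replace)].mean()
        for _ in range(runs)
    ]
    means = np.asarray(means)
    std = float(means.std(ddof=1)) if runs > 1 else 0.0
    return float(means.mean()), std


def write_report(result: EvalResult, csv_path: str, json_path: str | None = None) -> None:
    """Evaluation report as CSV (per assay) and JSON (summary)."""
    result.to_frame().to_csv(csv_path, index=False)
    if json_path is not None:
        import json

        with open(json_path, "w") as fh:
            json.dump(
                {
                    "macro_mean": result.macro_mean,
                    "bootstrap_mean": result.bootstrap_mean,
                    "bootstrap_std": result.bootstrap_std,
                    "n_assays": len(result.per_assay_rho),
                },
                fh,
                indent=2,
            )
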