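"""End-to-end comparison runs: simulate/load -> select -> classify -> evaluate.

:func:`run_comparison` evaluates every requested method (keyword rules per
tier, the ICD baseline, and the four TF-IDF classifiers per dataset variant)
on literally the same held-out test notes, and returns one metrics row per
method × tier together with a reproducibility manifest (seed, config hash,
library versions, test note ids).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .baselines import ICDCodeSet, classify_by_icd, classify_by_keywords, load_packaged_icd_codes
from .evaluation import BootstrapSpec, MetricsReport, bootstrap_metrics
from .lexicon import load_packaged_lexicon
from .modeling import MODEL_TYPES, NoteClassifier, SplitSpec, TfidfConfig, split_indices
from .synthetic import SynthConfig, generate_corpus
from .textprep import Note

__all__ = ["RunConfig", "run_comparison", "PipelineError"]

RULE_METHODS = ("keywords-base", "keywords-strict", "keywords-all", "icd")
DEFAULT_METHODS = ("keywords-all", "icd", "logreg", "random_forest", "mlp", "xgboost")


class PipelineError(RuntimeError):
    """A stage failure, named after the stage that raised it."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """One comparison run: input source, methods, tiers, splits, outputs."""

    synth: SynthConfig | None = None
    notes: Sequence[Note] | None = None
    methods: tuple[str, ...] = DEFAULT_METHODS
    tiers: tuple[str, ...] = ("full", "broad", "base")
    split: SplitSpec | None = None
    bootstrap: BootstrapSpec | None = None
    tfidf: TfidfConfig = field(default_factory=TfidfConfig)
    icd_codes: ICDCodeSet | None = None
    out_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.synth is None) == (self.notes is None):
            raise ValueError("exactly one of synth / notes must be given")
        if not self.methods or not self.tiers:
            raise ValueError("at least one method and one tier are required")
        for m in self.methods:
            if m not in RULE_METHODS and m not in MODEL_TYPES:
                raise ValueError(f"unknown method {m!r}")
        for t in self.tiers:
            if t not in ("full", "broad", "base"):
                raise ValueError(f"unknown tier {t!r}")


def _config_hash(cfg: RunConfig) -> str:
    payload = {
        "synth": asdict(cfg.synth) if cfg.synth else None,
        "methods": cfg.methods,
        "tiers": cfg.tiers,
        "split": asdict(cfg.split) if cfg.split else None,
        "bootstrap": asdict(cfg.bootstrap) if cfg.bootstrap else None,
        "tfidf": asdict(cfg.tfidf),
        "seed": cfg.seed,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[
        :16
    ]


def _metrics_row(method: str, tier: str, report: MetricsReport) -> dict:
    row: dict = {"method": method, "tier": tier}
    for m, v in report.point.items():
        row[m] = v
    for m in report.ci_low:
        row[f"{m}_ci_low"] = report.ci_low[m]
        row[f"{m}_ci_high"] = report.ci_high[m]
    return row


def _rule_report(y_true, y_pred, bootstrap: BootstrapSpec | None) -> MetricsReport:
    from .evaluation import confusion_metrics

    if bootstrap is not None:
        # 0/1 predictions act as degenerate scores; AUROC/AUPRC are then the
        # rank statistics of the binary rule itself.
        return bootstrap_metrics(y_true, np.asarray(y_pred, dtype=float), bootstrap)
    return confusion_metrics(y_true, y_pred)


def run_comparison(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Run every method on a shared test split; return (table, manifest)."""
    try:
        notes = list(config.notes) if config.notes is not None else generate_corpus(config.synth)
    except Exception as exc:
        raise PipelineError("input", str(exc)) from exc
    if any(n.label is None for n in notes):
        raise PipelineError("input", "every note needs a gold label for a comparison run")
    y = np.asarray([1 if n.label == "case" else 0 for n in notes])

    split = config.split if config.split is not None else SplitSpec(seed=config.seed)
    try:
        tr, va, te = split_indices(y, split)
    except Exception as exc:
        raise PipelineError("split", str(exc)) from exc
    test_notes = [notes[i] for i in te]
    y_test = y[te]

    rows: list[dict] = []
    predictions: dict[str, pd.DataFrame] = {}
    for method in config.methods:
        if method in RULE_METHODS:
            try:
                if method == "icd":
                    codes = config.icd_codes or load_packaged_icd_codes()
                    y_pred = np.asarray(
                        [int(classify_by_icd(n.icd_codes, codes)) for n in test_notes]
                    )
                else:
                    lex_tier = method.split("-", 1)[1]
                    lex = load_packaged_lexicon("all" if lex_tier == "all" else lex_tier)
                    y_pred = np.asarray(
                        [int(classify_by_keywords(n, lex)) for n in test_notes]
                    )
                report = _rule_report(y_test, y_pred, config.bootstrap)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"baseline:{method}", str(exc)) from exc
            rows.append(_metrics_row(method, "-", report))
            predictions[method] = pd.DataFrame(
                {
                    "note_id": [n.note_id for n in test_notes],
                    "y_true": y_test,
                    "score": y_pred.astype(float),
                    "label": y_pred,
                }
            )
        else:
            for tier in config.tiers:
                try:
                    clf = NoteClassifier(
                        notes,
                        labels=y,
                        tier=tier,
                        model_type=method,
                        tfidf=config.tfidf,
                        split=split,
                        seed=config.seed,
                    )
                    res = clf.fit(bootstrap=config.bootstrap)
                except Exception as exc:
                    raise PipelineError(f"train:{method}:{tier}", str(exc)) from exc
                assert res.test_note_ids == [n.note_id for n in test_notes]
                rows.append(_metrics_row(method, tier, res.metrics))
                predictions[f"{method}-{tier}"] = res.predictions

    table = pd.DataFrame(rows)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_notes": len(notes),
        "split_sizes": {"train": len(tr), "validation": len(va), "test": len(te)},
        "test_note_ids": [n.note_id for n in test_notes],
        "methods": list(config.methods),
        "tiers": list(config.tiers),
        "library_versions": _library_versions(),
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "comparison.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for name, df in predictions.items():
            df.to_csv(out / f"predictions_{name}.csv", index=False)
    return table, manifest


def _library_versions() -> dict[str, str]:
    import sklearn
    import xgboost

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "xgboost": xgboost.__version__,
    }
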