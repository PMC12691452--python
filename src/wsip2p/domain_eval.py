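"""Leave-one-domain-out generalization protocol and its derived tables.

Each domain is held out as the test set in turn while a model is trained
on the remaining domains. The derived columns mirror the reporting
conventions of multi-institution histopathology studies:

* domain gap:   reference accuracy (best domain) minus a domain's
  accuracy, in percentage points; the maximum gap is the accuracy range;
* Delta-1:      difference from a designated *source* domain's accuracy;
* Delta-2:      difference from a *best reference* accuracy (typically a
  study's best overall result, possibly from another experiment);
* consistency:  a gap of 0-9 percentage points is labeled "high", above 9
  "medium".

"Relative difference" is implemented as an absolute difference in
percentage points, the only reading consistent with the published
worked values (e.g. 85.2 - 83.9 = 1.3 and 95.72 - 85.2 = 10.52).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregators import AggregatorConfig
from .model import BackboneConfig, MILModel, TrainConfig, evaluate, train

HIGH_CONSISTENCY_MAX = 9.0  # percentage points; boundary itself is "high"


@dataclass
class DomainResult:
    """Held-out-domain metrics, as percentages in [0, 100]."""

    domain_id: str
    accuracy: float
    balanced_accuracy: float
    auroc: float
    f1: float

    def __post_init__(self) -> None:
        for name in ("accuracy", "balanced_accuracy", "auroc", "f1"):
            v = getattr(self, name)
            if np.isfinite(v) and not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be a percentage in [0, 100], got {v}")


@dataclass
class DomainReport:
    results: list[DomainResult]
    gaps: pd.DataFrame = field(default=None)
    deltas: pd.DataFrame = field(default=None)
    summary: pd.DataFrame = field(default=None)


def _accuracies(results) -> dict[str, float]:
    if isinstance(results, dict):
        return {str(k): float(v) for k, v in results.items()}
    return {r.domain_id: r.accuracy for r in results}


def run_cross_domain(
    bags: list[dict],
    train_config: TrainConfig,
    backbone: BackboneConfig = BackboneConfig(),
    aggregator: AggregatorConfig = AggregatorConfig(),
    seed: int = 0,
) -> list[DomainResult]:
    """Train on all-but-one domain, test on the held-out one, per domain.

    ``bags`` are feature-bag dicts carrying ``domain_id``. A domain
    without test bags is rejected.
    """
    domains = sorted({b["domain_id"] for b in bags})
    if len(domains) < 2:
        raise ValueError(f"need >= 2 domains, got {domains}")
    results = []
    for d in domains:
        test = [b for b in bags if b["domain_id"] == d]
        rest = [b for b in bags if b["domain_id"] != d]
        if not test:
            raise ValueError(f"domain {d} has no test bags")
        model = MILModel(backbone=backbone, aggregator=aggregator, seed=seed)
        model, _ = train(rest, [], train_config, model)
        rep = evaluate(model, test)
        results.append(DomainResult(
            domain_id=f"D{d}",
            accuracy=100.0 * rep.accuracy,
            balanced_accuracy=100.0 * rep.balanced_accuracy,
            auroc=100.0 * rep.auroc if np.isfinite(rep.auroc) else float("nan"),
            f1=100.0 * rep.f1,
        ))
    return results


def domain_gaps(results) -> pd.DataFrame:
    """Per-domain gap from the best-accuracy (reference) domain.

    The reference domain's gap is NaN (printed "-"); the maximum gap
    equals the range of the accuracies. Accepts DomainResult lists or a
    ``{domain: accuracy}`` mapping.
    """
    acc = _accuracies(results)
    if len(acc) < 2:
        raise ValueError("need >= 2 domains to compute gaps")
    reference = max(acc, key=acc.get)
    ref_acc = acc[reference]
    rows = [
        {"domain": d, "accuracy": a,
         "gap": np.nan if d == reference else ref_acc - a}
        for d, a in acc.items()
    ]
    out = pd.DataFrame(rows)
    out.attrs["reference"] = reference
    out.attrs["max_gap"] = float(ref_acc - min(acc.values()))
    return out


def consistency_label(delta: float) -> str:
    """0-9 percentage points (inclusive) -> "high"; above 9 -> "medium"."""
    return "high" if delta <= HIGH_CONSISTENCY_MAX else "medium"


def delta_table(results, source_domain: str, best_accuracy: float) -> pd.DataFrame:
    """Delta-1 (from the source domain) and Delta-2 (from the best
    reference accuracy) per domain, with (label1, label2) consistency pairs.

    The source row's Delta-1 is NaN and its first label "-".
    """
    acc = _accuracies(results)
    if source_domain not in acc:
        raise ValueError(f"source domain {source_domain!r} not among {sorted(acc)}")
    src = acc[source_domain]
    rows = []
    for d, a in acc.items():
        d1 = np.nan if d == source_domain else src - a
        d2 = best_accuracy - a
        rows.append({
            "domain": d, "accuracy": a, "delta1": d1, "delta2": d2,
            "consistency": (
                "-" if d == source_domain else consistency_label(d1),
                consistency_label(d2),
            ),
        })
    return pd.DataFrame(rows)


def summarize(results, gaps: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean and sample (n-1) standard deviation per metric column.

    The gap summary excludes the reference domain's empty entry. Accepts
    DomainResult lists, a mapping, or a plain sequence of values (summarized
    as a single "value" column).
    """
    if isinstance(results, (list, tuple)) and results and not isinstance(
        results[0], DomainResult
    ):
        frame = pd.DataFrame({"value": np.asarray(results, dtype=float)})
    elif isinstance(results, dict):
        frame = pd.DataFrame({"accuracy": list(_accuracies(results).values())})
    else:
        frame = pd.DataFrame([
            {"accuracy": r.accuracy, "balanced_accuracy": r.balanced_accuracy,
             "auroc": r.auroc, "f1": r.f1}
            for r in results
        ])
    if gaps is not None:
        frame = frame.copy()
        gap_vals = gaps["gap"].dropna().to_numpy()
        frame2 = pd.DataFrame({"gap": gap_vals})
    rows = []
    for col in frame.columns:
        v = frame[col].dropna().to_numpy()
        rows.append({"metric": col, "mean": float(np.mean(v)),
                     "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0})
    if gaps is not None and len(frame2):
        v = frame2["gap"].to_numpy()
        rows.append({"metric": "gap", "mean": float(np.mean(v)),
                     "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0})
    return pd.DataFrame(rows)


def domain_report(
    results, source_domain: str, best_accuracy: float
) -> DomainReport:
    """Bundle gaps, delta table and summary for a cross-domain run."""
    if isinstance(results, (list, tuple)) and results and isinstance(
        results[0], DomainResult
    ):
        res = list(results)
    else:
        res = [DomainResult(d, a, float("nan"), float("nan"), float("nan"))
               for d, a in _accuracies(results).items()]
    gaps = domain_gaps(results)
    return DomainReport(
        results=res,
        gaps=gaps,
        deltas=delta_table(results, source_domain, best_accuracy),
        summary=summarize(results, gaps),
    )
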