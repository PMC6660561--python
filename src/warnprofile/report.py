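"""Chart and table outputs: the two five-bin bar charts per strategy and a
tidy CSV/JSON summary mirroring the characterization tables."""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

import pandas as pd

from .core import (
    NA_TOKEN,
    BinCounts,
    Category,
    CATEGORY_ORDER,
    ProfilePair,
    TraditionalMetrics,
    ValidationError,
    round_half_even,
)

# keep SVG ids reproducible across runs
matplotlib.rcParams["svg.hashsalt"] = "warnprofile"

_BIN_LABELS = [c.value for c in CATEGORY_ORDER]


def _slug(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", name.lower()).strip("_")


def _save(fig, base: Path, formats) -> list[Path]:
    written = []
    for ext in formats:
        out = base.with_suffix(f".{ext}")
        metadata = {"Date": None} if ext == "svg" else None
        fig.savefig(out, metadata=metadata)
        written.append(out)
    return written


def render_profiles(
    profiles: Mapping[str, ProfilePair],
    path,
    formats: tuple[str, ...] = ("png", "svg"),
) -> list[Path]:
    """Write one bar chart per strategy per profile type.

    Bins are drawn in the order False, Early, On Time, Late, Missed.
    Identical inputs produce identical files. Returns the written paths.
    """
    if not profiles:
        raise ValidationError("no strategies to render")
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, pair in profiles.items():
        specs = (
            ("warning_proportions", pair.warning_proportions, "Warning proportion"),
            ("warnings_per_record", pair.warnings_per_record, "Warnings per record"),
        )
        for kind, profile, ylabel in specs:
            values = [profile[c] for c in CATEGORY_ORDER]
            fig, ax = plt.subplots(figsize=(5, 3.5))
            ax.bar(_BIN_LABELS, values, color="0.35")
            ax.set_ylabel(ylabel)
            ax.set_title(f"{name} — {ylabel.lower()}")
            if kind == "warning_proportions":
                ax.set_ylim(0, max(1.0, max(values) * 1.05))
            else:
                ax.set_ylim(0, max(1.0, max(values) * 1.1))
            fig.tight_layout()
            written.extend(_save(fig, outdir / f"{_slug(name)}_{kind}", formats))
            plt.close(fig)
    return written


def _metrics_dict(m: TraditionalMetrics) -> dict:
    def pct(x: float | None) -> float | None:
        return None if x is None else round_half_even(x, 1)

    return {
        "n_true_positive_records": m.n_true_positive_records,
        "n_false_positive_records": m.n_false_positive_records,
        "n_event_records": m.n_event_records,
        "n_nonevent_records": m.n_nonevent_records,
        "ppv_percent": pct(m.ppv),
        "sensitivity_percent": pct(m.sensitivity),
        "false_positive_rate_percent": pct(m.false_positive_rate),
    }


def write_summary(
    counts: Mapping[str, BinCounts],
    profiles: Mapping[str, ProfilePair | None],
    metrics: Mapping[str, TraditionalMetrics] | None,
    csv_path,
    json_path=None,
) -> None:
    """Write the tidy per-bin CSV and a JSON summary.

    ``profiles[name]`` may be ``None`` for a strategy with zero warnings;
    its proportion column is emitted as NA. All strategy maps must share
    the same key set.
    """
    if set(counts) != set(profiles):
        raise ValidationError("counts and profiles must cover the same strategies")
    if metrics is not None and set(metrics) != set(counts):
        raise ValidationError("metrics must cover the same strategies")
    rows = []
    summary: dict = {"strategies": {}}
    for name, c in counts.items():
        pair = profiles[name]
        for cat, n in c.by_category().items():
            n_records = (
                c.n_nonevent_records if cat is Category.FALSE else c.n_event_records
            )
            prop = (
                round_half_even(pair.warning_proportions[cat], 2) if pair else None
            )
            per_rec = (
                round_half_even(pair.warnings_per_record[cat], 2) if pair else None
            )
            rows.append(
                {
                    "strategy": name,
                    "category": cat.value,
                    "n_warnings": n,
                    "total_warnings": c.total_warnings,
                    "n_records": n_records,
                    "warning_proportion": prop,
                    "warnings_per_record": per_rec,
                }
            )
        entry = {
            "counts": {cat.value: n for cat, n in c.by_category().items()},
            "total_warnings": c.total_warnings,
            "n_event_records": c.n_event_records,
            "n_nonevent_records": c.n_nonevent_records,
            "warning_proportions": (
                {cat.value: pair.warning_proportions[cat] for cat in CATEGORY_ORDER}
                if pair
                else None
            ),
            "warnings_per_record": (
                {cat.value: pair.warnings_per_record[cat] for cat in CATEGORY_ORDER}
                if pair
                else None
            ),
            "undefined_bins": sorted(b.value for b in pair.undefined_bins)
            if pair
            else [],
        }
        if metrics is not None:
            entry["traditional_metrics"] = _metrics_dict(metrics[name])
        summary["strategies"][name] = entry
    pd.DataFrame(rows).to_csv(csv_path, index=False, na_rep=NA_TOKEN)
    if json_path is None:
        json_path = Path(csv_path).with_suffix(".json")
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
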