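"""Run configuration and report assembly.

A run emits a small bundle of plain files: a summary table of weighted
degree per scenario cell (n, mean ± sd), a p-value table, the habitat
table, the full null-coefficient draws for audit, null-distribution
histograms with the observed coefficient overlaid, network drawings, and a
machine-readable JSON holding every number at full precision.  Every file
set is stamped with the seed and a hash of the configuration so outputs are
traceable to the exact settings that produced them.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .data_io import StudyWindow
from .habitat_stats import RankSumResult
from .network_core import simple_ratio_index
from .permutation_inference import BaciConfig, BaciResult

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Validated settings for a full analysis run."""

    windows: dict = field(default_factory=dict)  # label -> StudyWindow
    arms: tuple[str, ...] = ("affected", "unaffected")
    affected_radius_m: float = 100.0
    unaffected_radius_m: float = 500.0
    min_sightings: int = 2
    n_permutations: int = 1000
    swaps_per_permutation: int = 1
    burn_in: int = 0
    tails: tuple[tuple[str, str], ...] = (("affected", "greater"), ("unaffected", "less"))
    seed: int = 0
    strict: bool = True
    study_year: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.affected_radius_m < self.unaffected_radius_m:
            raise ValueError("radii must satisfy 0 < affected < unaffected")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.min_sightings < 1:
            raise ValueError("min_sightings must be >= 1")
        for arm, tail in self.tails:
            if tail not in ("greater", "less"):
                raise ValueError(f"tail for {arm!r} must be greater/less")

    def baci(self) -> BaciConfig:
        return BaciConfig(
            arms=self.arms,
            affected_radius_m=self.affected_radius_m,
            unaffected_radius_m=self.unaffected_radius_m,
            min_sightings=self.min_sightings,
            n_permutations=self.n_permutations,
            swaps_per_permutation=self.swaps_per_permutation,
            burn_in=self.burn_in,
            tails=tuple((a, t) for a, t in self.tails),  # type: ignore[arg-type]
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        d = {
            "arms": list(self.arms),
            "affected_radius_m": self.affected_radius_m,
            "unaffected_radius_m": self.unaffected_radius_m,
            "min_sightings": self.min_sightings,
            "n_permutations": self.n_permutations,
            "swaps_per_permutation": self.swaps_per_permutation,
            "burn_in": self.burn_in,
            "tails": {a: t for a, t in self.tails},
            "seed": self.seed,
            "strict": self.strict,
            "study_year": self.study_year,
            "windows": {
                label: {
                    "start": w.start_date.isoformat(),
                    "end": w.end_date.isoformat(),
                }
                for label, w in self.windows.items()
            },
        }
        return d

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        windows = {}
        for label, spec in (raw.pop("windows", {}) or {}).items():
            windows[label] = StudyWindow(
                label=label,
                start_date=dt.date.fromisoformat(str(spec["start"])),
                end_date=dt.date.fromisoformat(str(spec["end"])),
            )
        tails = tuple((a, t) for a, t in (raw.pop("tails", {}) or {}).items()) or cls.tails
        arms = tuple(raw.pop("arms", ("affected", "unaffected")))
        known = {
            k: raw[k]
            for k in (
                "affected_radius_m", "unaffected_radius_m", "min_sightings",
                "n_permutations", "swaps_per_permutation", "burn_in", "seed",
                "strict", "study_year",
            )
            if k in raw
        }
        return cls(windows=windows, arms=arms, tails=tails, **known)


def _round2(x: float) -> float:
    return float(np.round(x, 2))


def summary_table(result: BaciResult) -> pd.DataFrame:
    """Table of weighted degree per scenario cell: n, mean ± sd (2 dp)."""
    rows = [
        {
            "scenario": cell["scenario"],
            "period": cell["period"],
            "n": cell["n"],
            "mean_weighted_degree": _round2(cell["mean_weighted_degree"]),
            "sd_weighted_degree": _round2(cell["sd_weighted_degree"]),
        }
        for cell in result.summary
    ]
    return pd.DataFrame(
        rows, columns=["scenario", "period", "n", "mean_weighted_degree", "sd_weighted_degree"]
    )


def pvalue_table(result: BaciResult) -> pd.DataFrame:
    rows = [
        {
            "scenario": t.label,
            "metric": t.metric,
            "observed_coef": t.observed_coef,
            "tail": t.tail,
            "p_one_tailed": t.p_one_tailed,
            "n_permutations": t.n_permutations,
        }
        for t in result.tests
    ]
    return pd.DataFrame(
        rows,
        columns=["scenario", "metric", "observed_coef", "tail", "p_one_tailed", "n_permutations"],
    )


def habitat_table(habitat_results: list[dict]) -> pd.DataFrame:
    rows = []
    for entry in habitat_results:
        if entry.get("skipped"):
            rows.append({"comparison": entry["comparison"], "skipped": True})
            continue
        res: RankSumResult = entry["result"]
        rows.append(
            {
                "comparison": entry["comparison"],
                "skipped": False,
                "W": res.w_statistic,
                "U": res.u_statistic,
                "p_value": res.p_value,
                "n1": res.n1,
                "n2": res.n2,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def assemble_report(
    result: BaciResult | None,
    habitat_results: list[dict] | None,
    config: RunConfig,
    outdir: str | Path,
    figures: bool = True,
) -> dict:
    """Write the full report bundle to *outdir*; returns the report dict.

    On a write failure the partially written directory is removed so a
    half-report can never be mistaken for a complete one.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    created = not any(outdir.iterdir())
    try:
        report: dict = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
        }
        if result is not None:
            table1 = summary_table(result)
            pvals = pvalue_table(result)
            table1.to_csv(outdir / "degree_summary.csv", index=False)
            pvals.to_csv(outdir / "pvalues.csv", index=False)
            nulls = pd.DataFrame(
                {
                    f"{t.label}:{t.metric}": t.null_coefs
                    for t in result.tests
                }
            )
            nulls.to_csv(outdir / "null_coefficients.csv", index=False)
            report["degree_summary"] = table1.to_dict(orient="records")
            report["tests"] = [
                {
                    "scenario": t.label,
                    "metric": t.metric,
                    "observed_coef": t.observed_coef,
                    "tail": t.tail,
                    "p_one_tailed": t.p_one_tailed,
                    "n_permutations": t.n_permutations,
                    "swaps_per_permutation": t.swaps_per_permutation,
                    "seed": t.seed,
                }
                for t in result.tests
            ]
            report["missing_scenarios"] = list(result.missing)
            if figures:
                _null_histograms(result, outdir)
                _network_drawings(result, outdir)
        if habitat_results is not None:
            htable = habitat_table(habitat_results)
            htable.to_csv(outdir / "habitat.csv", index=False)
            report["habitat"] = htable.to_dict(orient="records")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        return report
    except OSError:
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        raise


def _null_histograms(result: BaciResult, outdir: Path) -> None:
    """Null-coefficient histogram per test with the observed slope overlaid."""
    for t in result.tests:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.hist(t.null_coefs, bins=30, color="0.7", edgecolor="0.4")
        ax.axvline(t.observed_coef, color="red", lw=2)
        ax.set_xlabel(f"null {t.metric} coefficient")
        ax.set_ylabel("frequency")
        ax.set_title(f"{t.label}: p={t.p_one_tailed:.3g} ({t.tail})")
        fig.tight_layout()
        fig.savefig(outdir / f"null_hist_{t.label}_{t.metric}.png", dpi=100)
        plt.close(fig)


def _network_drawings(result: BaciResult, outdir: Path) -> None:
    for (arm, period), gbi in result.gbis.items():
        assoc = simple_ratio_index(gbi)
        g = assoc.to_graph()
        fig, ax = plt.subplots(figsize=(5, 5))
        pos = nx.spring_layout(g, seed=0)
        widths = [3.0 * g[u][v]["weight"] for u, v in g.edges]
        nx.draw_networkx(
            g, pos=pos, ax=ax, node_size=60, with_labels=False,
            width=widths, node_color="#c04040" if arm == "affected" else "#4060c0",
        )
        ax.set_title(f"{arm} {period} (n={gbi.n_individuals})")
        ax.axis("off")
        fig.tight_layout()
        fig.savefig(outdir / f"network_{arm}_{period}.png", dpi=100)
        plt.close(fig)
        nx.write_graphml(g, outdir / f"network_{arm}_{period}.graphml")
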