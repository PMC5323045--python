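"""End-to-end orchestration over directories of reconstructions.

Runs the morphometric battery per neuron, writes a one-row-per-neuron
summary CSV plus long-format distribution CSVs and subtree bootstrap
JSON, and records provenance (config hash, seeds, package versions).
Group comparisons across cell types are descriptive delegations to
standard routines: one-way ANOVA when Levene's test accepts variance
homogeneity at alpha = 0.05, otherwise Kruskal-Wallis, with Tukey HSD
pairwise letters.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import morphometrics as mm
from .geometry import CELL_TYPES, NeuronGeometry, SkeletonError, validate
from .io import parse_hoc, parse_swc, tag_axons

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    inputs: list[str]  # SWC or hoc files
    cell_types: dict[str, str] = field(default_factory=dict)  # filename -> label
    output_dir: str = "stgmorph_out"
    seed: int = 0
    run_subtrees: bool = True
    run_mst: bool = False
    n_scrambles: int = 2000
    sholl_bins: int = 100
    auto_tag_axons: bool = True
    min_axon_length: float = 20.0

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items()}, sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_reconstruction(path: str | Path, cell_type: str = "other") -> NeuronGeometry:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".swc":
        return parse_swc(text, label=path.stem, cell_type=cell_type)
    return parse_hoc(text, label=path.stem, cell_type=cell_type)


def run_analysis(config: RunConfig) -> dict:
    """Process every input file; skip (and log) files failing validation.

    Returns a dict of output paths; writes summary.csv, paths.csv,
    angles.csv, symmetry.csv, sholl.csv, subtrees.json, provenance.json
    under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    summaries, path_rows, angle_rows, si_rows, sholl_rows = [], [], [], [], []
    subtree_reports = {}
    skipped = []

    for fname in config.inputs:
        label = Path(fname).stem
        ctype = config.cell_types.get(fname, config.cell_types.get(label, "other"))
        if ctype not in CELL_TYPES:
            ctype = "other"
        try:
            geom = load_reconstruction(fname, cell_type=ctype)
            report = validate(geom)
            if not report.ok:
                raise SkeletonError(
                    "; ".join(f.message for f in report.findings)
                )
        except (SkeletonError, OSError, ValueError) as exc:
            logger.error("skipping %s: %s", fname, exc)
            skipped.append({"file": str(fname), "error": str(exc)})
            continue

        if config.auto_tag_axons and not geom.axon_segment_ids:
            tag_axons(geom, min_unbranched_length=config.min_axon_length, auto_tag=True)

        summaries.append(mm.summarize(geom).to_row())
        for p in mm.enumerate_paths(geom):
            path_rows.append(
                {
                    "label": label,
                    "tip": p.tip_node_id,
                    "path_length_um": p.path_length,
                    "euclidean_um": p.euclidean_distance,
                    "tortuosity": p.tortuosity,
                    "branch_order_at_tip": p.branch_order_at_tip,
                }
            )
        for a in mm.branch_angles(geom):
            angle_rows.append({"label": label, **a})
        for bp, s in mm.symmetry_indices(geom).items():
            si_rows.append({"label": label, "branch_point": bp, "symmetry_index": s})
        prof = mm.linearized_sholl(geom, n_distances=config.sholl_bins)
        for d, c in zip(prof.distances, prof.counts):
            sholl_rows.append({"label": label, "distance_um": float(d), "crossings": int(c)})

        if config.run_subtrees and geom.axon_segment_ids:
            from .subtrees import field_report

            subtree_reports[label] = field_report(
                geom, n_iterations=config.n_scrambles, seed=config.seed
            )

    outputs = {}
    for name, rows in [
        ("summary", summaries),
        ("paths", path_rows),
        ("angles", angle_rows),
        ("symmetry", si_rows),
        ("sholl", sholl_rows),
    ]:
        p = out / f"{name}.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        outputs[name] = str(p)
    if subtree_reports:
        p = out / "subtrees.json"
        p.write_text(json.dumps(subtree_reports, indent=2))
        outputs["subtrees"] = str(p)

    import stgmorph

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_inputs": len(config.inputs),
        "n_processed": len(summaries),
        "skipped": skipped,
        "package_version": getattr(stgmorph, "__version__", "unknown"),
        "numpy_version": np.__version__,
        "elapsed_s": round(time.time() - t0, 3),
    }
    p = out / "provenance.json"
    p.write_text(json.dumps(provenance, indent=2))
    outputs["provenance"] = str(p)
    return outputs


# ----------------------------------------------------------- group tests

@dataclass
class GroupComparison:
    metric: str
    groups: dict[str, np.ndarray]
    test_used: str  # "anova" | "kruskal"
    statistic: float
    p_value: float
    levene_p: float
    posthoc: pd.DataFrame | None  # Tukey HSD pairwise table
    letters: dict[str, str]


def group_compare(samples_by_group: dict[str, np.ndarray], metric: str = "") -> GroupComparison:
    """Compare a metric across cell types.

    One-way ANOVA when Levene's test accepts homoscedasticity (p > 0.05),
    else Kruskal-Wallis; Tukey HSD post-hoc with compact letter display
    (groups sharing a letter are not significantly different).
    """
    groups = {k: np.asarray(v, float) for k, v in samples_by_group.items()}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    arrays = list(groups.values())
    levene_p = float(stats.levene(*arrays).pvalue)
    if levene_p > 0.05:
        res = stats.f_oneway(*arrays)
        test, stat, p = "anova", float(res.statistic), float(res.pvalue)
    else:
        res = stats.kruskal(*arrays)
        test, stat, p = "kruskal", float(res.statistic), float(res.pvalue)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(arrays)
    labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
    tk = pairwise_tukeyhsd(values, labels, alpha=0.05)
    posthoc = pd.DataFrame(
        tk.summary().data[1:], columns=tk.summary().data[0]
    )
    letters = _tukey_letters(groups.keys(), posthoc)
    return GroupComparison(metric, groups, test, stat, p, levene_p, posthoc, letters)


def _tukey_letters(group_names, posthoc: pd.DataFrame) -> dict[str, str]:
    """Compact letter display from pairwise reject flags (greedy insertion)."""
    names = sorted(group_names)
    differs = {
        frozenset((r["group1"], r["group2"])): bool(r["reject"])
        for _, r in posthoc.iterrows()
    }
    letter_sets: list[set[str]] = []
    for g in names:
        placed = False
        for s in letter_sets:
            if all(not differs.get(frozenset((g, h)), False) for h in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    letters = {g: "" for g in names}
    for i, s in enumerate(letter_sets):
        for g in sorted(s):
            letters[g] += chr(ord("a") + i)
    return letters
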