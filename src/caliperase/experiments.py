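"""Seeded condition-grid experiments: the detection and classification studies.

Six dataset conditions derive from one phantom dataset:

========  ===========================================================
A0        marker-layered training images (calipers burned at nodules)
A1        training images with markers removed via the oracle mask
          (stand-in for careful manual removal)
A2        training images with markers auto-located, then inpainted
A3        marker-mixup training images (structure destroyed)
B1        marker-layered test images
B2        marker-free test images (the raw phantoms)
========  ===========================================================

The detection study trains one detector per training condition per seed and
evaluates on B1/B2 at IoU 0.3 and 0.4; the classification study trains the
baseline and VIB crop classifiers on marker-layered positives + pseudo-
marker negatives and evaluates the six test-set manipulation cases. Ordering
claims (the marker-shortcut gap and its suppression) are decided by
one-sided across-seed sign tests at alpha = 0.05.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from caliperase import annotate, detect, evalx, inpaint, phantom, vib

CASE_SPECS = {
    1: ("baseline", "neg_pseudo", "pos_layered"),
    2: ("baseline", "neg_asis", "pos_layered"),
    3: ("baseline", "neg_asis", "pos_free"),
    4: ("vib", "neg_pseudo", "pos_layered"),
    5: ("vib", "neg_asis", "pos_layered"),
    6: ("vib", "neg_asis", "pos_free"),
}


def sign_test(successes: int, n: int) -> float:
    """One-sided sign-test p-value for ``successes`` out of ``n`` comparisons."""
    return float(stats.binom.sf(successes - 1, n, 0.5))


def _config_hash(obj) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, tuple):
            return list(o)
        return str(o)
    blob = json.dumps(obj, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    rows: list[dict]
    summary: dict
    ordering: dict
    seeds: list[int]
    config_hash: str

    def to_json(self) -> str:
        return json.dumps({"rows": self.rows, "summary": self.summary,
                           "ordering": self.ordering, "seeds": self.seeds,
                           "config_hash": self.config_hash}, sort_keys=True, indent=1)

    def to_markdown(self) -> str:
        if not self.rows:
            return "(empty report)"
        cols = list(self.rows[0].keys())
        lines = ["| " + " | ".join(cols) + " |",
                 "|" + "|".join("---" for _ in cols) + "|"]
        for row in self.rows:
            lines.append("| " + " | ".join(
                f"{row[c]:.2f}" if isinstance(row[c], float) else str(row[c])
                for c in cols) + " |")
        return "\n".join(lines)


@dataclass
class ConditionGrid:
    """The six dataset variants; ground truth is shared within each split."""

    train: dict[str, list[np.ndarray]]          # A0..A3 -> images
    train_nodules: list[list[phantom.Nodule]]
    test: dict[str, list[np.ndarray]]           # B1, B2 -> images
    test_nodules: list[list[phantom.Nodule]]
    seed: int


def build_condition_grid(dataset: phantom.PhantomDataset, seed: int = 0,
                         glyph: annotate.MarkerGlyph | None = None,
                         tex_params: inpaint.TexSynthParams | None = None,
                         mask_dilation: int = 1) -> ConditionGrid:
    """Derive the A0-A3 / B1-B2 variants from one phantom dataset."""
    if glyph is None:
        glyph = annotate.MarkerGlyph()
    root = np.random.SeedSequence([seed, 0x617D])
    train_items, test_items = dataset.train, dataset.test
    seeds = root.spawn(len(train_items) + len(test_items))

    a0, a1, a2, a3 = [], [], [], []
    train_nodules = []
    for i, item in enumerate(train_items):
        rng = np.random.default_rng(seeds[i])
        s_ann, s_a1, s_a2, s_a3 = (int(v) for v in rng.integers(0, 2**31 - 1, 4))
        ann = annotate.annotate_phantom(item.image, item.nodules, glyph, seed=s_ann)
        a0.append(ann.image)
        train_nodules.append(item.nodules)
        oracle = annotate.marker_mask(ann.groups, glyph, item.image.shape,
                                      dilation=mask_dilation)
        a1.append(inpaint.inpaint_texture(ann.image, oracle, tex_params, seed=s_a1).image)
        located = inpaint.locate_markers(ann.image, [glyph])
        if located.any():
            a2.append(inpaint.inpaint_texture(ann.image, located, tex_params,
                                              seed=s_a2).image)
        else:
            a2.append(ann.image.copy())
        a3.append(annotate.mixup_markers(ann, seed=s_a3).image)

    b1, b2, test_nodules = [], [], []
    for j, item in enumerate(test_items):
        rng = np.random.default_rng(seeds[len(train_items) + j])
        s_ann = int(rng.integers(0, 2**31 - 1))
        ann = annotate.annotate_phantom(item.image, item.nodules, glyph, seed=s_ann)
        b1.append(ann.image)
        b2.append(item.image.copy())
        test_nodules.append(item.nodules)

    return ConditionGrid(train={"A0": a0, "A1": a1, "A2": a2, "A3": a3},
                         train_nodules=train_nodules,
                         test={"B1": b1, "B2": b2},
                         test_nodules=test_nodules, seed=seed)


@dataclass
class DetectionStudyConfig:
    detector: detect.DetectorConfig = field(default_factory=detect.DetectorConfig)
    conditions: tuple[str, ...] = ("A0", "A1", "A2", "A3")
    iou_thresholds: tuple[float, float] = (0.4, 0.3)
    headline_iou: float = 0.3


def _evaluate_condition(model: detect.DetectorModel, images: list[np.ndarray],
                        nodules: list[list[phantom.Nodule]],
                        iou_thresholds) -> dict:
    dets_by_image = {i: [d for d in detect.detect(img, model)]
                     for i, img in enumerate(images)}
    gts_by_image = {i: [n.bbox for n in nods] for i, nods in enumerate(nodules)}
    return evalx.evaluate_detections(dets_by_image, gts_by_image, iou_thresholds)


def run_detection_study(grid: ConditionGrid,
                        config: DetectionStudyConfig | None = None,
                        seeds: list[int] | None = None) -> RunReport:
    """Train per-condition detectors across seeds and evaluate on B1/B2.

    The report carries one row per (condition, test set, IoU, seed) plus
    seed-mean rows, and the marker-shortcut ordering statistics at the
    headline IoU.
    """
    if config is None:
        config = DetectionStudyConfig()
    if seeds is None:
        seeds = [0, 1, 2]
    if len(seeds) < 3:
        raise ValueError("detection study needs >= 3 seeds")

    rows = []
    metrics: dict[tuple, dict] = {}
    for cond in config.conditions:
        items = list(zip(grid.train[cond], grid.train_nodules))
        for seed in seeds:
            model = detect.train_detector(items, config.detector, seed=seed)
            for testset in ("B1", "B2"):
                res = _evaluate_condition(model, grid.test[testset],
                                          grid.test_nodules, config.iou_thresholds)
                metrics[(cond, testset, seed)] = res
                for t, m in res.items():
                    rows.append({"condition": cond, "testset": testset,
                                 "iou": t, "seed": seed,
                                 "mAP": 100 * m["mAP"], "recall": 100 * m["recall"],
                                 "fscore": 100 * m["fscore"]})

    hi = config.headline_iou
    def series(cond, testset):
        return np.array([metrics[(cond, testset, s)][hi]["mAP"] * 100 for s in seeds])

    summary = {}
    for cond in config.conditions:
        for testset in ("B1", "B2"):
            vals = series(cond, testset)
            summary[f"mAP_{testset}_{cond}"] = {
                "mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
                "per_seed": vals.tolist()}

    ordering = {}
    if "A0" in config.conditions:
        a0_gap = series("A0", "B1") - series("A0", "B2")
        ordering.update({
            "a0_gap_per_seed": a0_gap.tolist(),
            "a0_gap_mean": float(a0_gap.mean()),
            "a0_gap_positive_all_seeds": bool((a0_gap > 0).all()),
            "a0_gap_sign_p": sign_test(int((a0_gap > 0).sum()), len(seeds)),
        })
    if "A2" in config.conditions:
        a2_gap = series("A2", "B1") - series("A2", "B2")
        ordering["a2_gap_mean"] = float(np.abs(a2_gap).mean())
    if {"A0", "A2"} <= set(config.conditions):
        a2_vs_a0 = series("A2", "B2") - series("A0", "B2")
        ordering["a2_beats_a0_on_b2_all_seeds"] = bool((a2_vs_a0 > 0).all())
        if "A3" in config.conditions:
            a3_b2 = series("A3", "B2").mean()
            ordering["a3_b2_mean"] = float(a3_b2)
            ordering["a3_between_a0_and_a2_on_b2"] = bool(
                series("A0", "B2").mean() < a3_b2 < series("A2", "B2").mean())
    return RunReport(rows=rows, summary=summary, ordering=ordering,
                     seeds=list(seeds), config_hash=_config_hash(
                         {"detector": config.detector, "grid_seed": grid.seed}))


@dataclass
class ClassificationStudyConfig:
    """Crop benchmark mirroring the near-balanced clinical crop design."""

    phantom: phantom.PhantomConfig = field(default_factory=lambda: phantom.PhantomConfig(
        n_train=140, n_test=140))
    n_train_crops: int = 200      # per class (near-1:1, scaled from 872/895)
    n_test_crops: int = 200       # per class cap
    crop_margin: int = 6
    baseline: vib.ClassifierConfig = field(
        default_factory=lambda: vib.ClassifierConfig(use_vib=False, epochs=60))
    vib: vib.ClassifierConfig = field(
        default_factory=lambda: vib.ClassifierConfig(use_vib=True, epochs=60, beta=0.01))
    benchmark_seed: int = 0


@dataclass
class CropBenchmark:
    train_crops: np.ndarray
    train_labels: np.ndarray
    test_sets: dict[str, np.ndarray]   # pos_layered, pos_free, neg_asis, neg_pseudo


def _neg_window(rng, shape, boxes, side_range, max_attempts=100):
    h, w = shape
    for _ in range(max_attempts):
        s = int(rng.integers(side_range[0], side_range[1] + 1))
        if s > min(h, w):
            continue
        r0 = int(rng.integers(0, h - s + 1))
        c0 = int(rng.integers(0, w - s + 1))
        window = (c0, r0, c0 + s, r0 + s)
        if all(evalx.iou(window, b) == 0.0 for b in boxes):
            return r0, c0, s
    return None


def _pseudo_in_crop(crop: np.ndarray, max_dims, glyph, seed,
                    avoid: list[phantom.Nodule] | None = None) -> np.ndarray:
    """Burn a pseudo caliper group inside a marker-free crop.

    ``avoid`` lists blob structures whose boxes the pseudo rectangle must not
    intersect (the IoU-0 placement rule, applied to the local candidate
    region); infeasible placements fall back to unconstrained.
    """
    try:
        grp = annotate.generate_pseudo_group(crop, avoid or [], max_dims, seed=seed)
    except phantom.PlacementError:
        grp = annotate.generate_pseudo_group(crop, [], max_dims, seed=seed)
    burned, _ = annotate.burn_glyphs(crop, grp.points, glyph)
    return burned


def build_crop_benchmark(config: ClassificationStudyConfig,
                         glyph: annotate.MarkerGlyph | None = None) -> CropBenchmark:
    """Build the train/test crop sets for the six-case study.

    Training: marker-layered positives (calipers at the nodule bbox) and
    pseudo-marker negatives, near 1:1. Test: the marker-layered/marker-free
    positive versions and as-is/pseudo-added negative versions share crop
    geometry, so a case differs from another only by the manipulation.
    """
    if glyph is None:
        glyph = annotate.MarkerGlyph()
    ds = phantom.render_dataset(config.phantom, seed=config.benchmark_seed)
    root = np.random.SeedSequence([config.benchmark_seed, 0xC20B])
    rng = np.random.default_rng(root)
    side = config.baseline.input_side

    all_boxes = [n.bbox for it in ds.train for n in it.nodules]
    max_dims = (max(b[2] - b[0] for b in all_boxes), max(b[3] - b[1] for b in all_boxes))
    side_range = (min(b[2] - b[0] for b in all_boxes) + 2 * config.crop_margin,
                  max(b[3] - b[1] for b in all_boxes) + 2 * config.crop_margin)

    def crop_sets(items, n_cap):
        pos_layered, pos_free, neg_asis, neg_pseudo = [], [], [], []
        for item in items:
            s_ann = int(rng.integers(0, 2**31 - 1))
            ann = annotate.annotate_phantom(item.image, item.nodules, glyph, seed=s_ann)
            boxes = [n.bbox for n in item.nodules]
            for nod in item.nodules:
                if len(pos_layered) >= n_cap:
                    break
                r0, c0, s = detect._square_crop_bounds(nod.bbox, config.crop_margin,
                                                       item.image.shape)
                sl = (slice(r0, r0 + s), slice(c0, c0 + s))
                pos_layered.append(detect.resize_area(ann.image[sl], side))
                pos_free.append(detect.resize_area(item.image[sl], side))
            # negatives mimic detector proposals: centered on nodule-like
            # distractor structures when present, random background otherwise
            neg_centers = list(item.distractors) or [None]
            for dis in neg_centers:
                if len(neg_asis) >= n_cap:
                    break
                local_avoid: list[phantom.Nodule] = []
                if dis is not None:
                    r0, c0, s = detect._square_crop_bounds(
                        dis.bbox, config.crop_margin, item.image.shape)
                    window = (c0, r0, c0 + s, r0 + s)
                    if not all(evalx.iou(window, b) == 0.0 for b in boxes):
                        continue
                    local_avoid = [phantom.Nodule(
                        center=(dis.center[0] - r0, dis.center[1] - c0),
                        semi_axes=dis.semi_axes, rotation=dis.rotation,
                        contrast=dis.contrast)]
                else:
                    win = _neg_window(rng, item.image.shape, boxes, side_range)
                    if win is None:
                        continue
                    r0, c0, s = win
                raw = item.image[r0:r0 + s, c0:c0 + s]
                # pseudo rectangle sized like a nodule box, small enough to sit
                # anywhere in the crop (markers need not hug the crop border)
                pdims = (min(max_dims[0], max(8, s - 8)), min(max_dims[1], max(8, s - 8)))
                pseudo = _pseudo_in_crop(raw, pdims, glyph,
                                         seed=int(rng.integers(0, 2**31 - 1)),
                                         avoid=local_avoid)
                neg_asis.append(detect.resize_area(raw, side))
                neg_pseudo.append(detect.resize_area(pseudo, side))
        return (np.array(pos_layered), np.array(pos_free),
                np.array(neg_asis), np.array(neg_pseudo))

    tr_pl, _tr_pf, _tr_na, tr_np = crop_sets(ds.train, config.n_train_crops)
    te_pl, te_pf, te_na, te_np = crop_sets(ds.test, config.n_test_crops)

    n = min(len(tr_pl), len(tr_np))
    train_crops = np.concatenate([tr_pl[:n], tr_np[:n]])
    train_labels = np.concatenate([np.ones(n, dtype=int), np.zeros(n, dtype=int)])
    m = min(len(te_pl), len(te_na))
    return CropBenchmark(
        train_crops=train_crops, train_labels=train_labels,
        test_sets={"pos_layered": te_pl[:m], "pos_free": te_pf[:m],
                   "neg_asis": te_na[:m], "neg_pseudo": te_np[:m]})


def _case_accuracy(model: vib.VIBModel, bench: CropBenchmark,
                   neg_version: str, pos_version: str) -> float:
    neg = bench.test_sets[neg_version]
    pos = bench.test_sets[pos_version]
    crops = np.concatenate([neg, pos])
    labels = np.concatenate([np.zeros(len(neg), dtype=int), np.ones(len(pos), dtype=int)])
    return vib.accuracy(model, crops, labels)


def run_classification_study(config: ClassificationStudyConfig | None = None,
                             seeds: list[int] | None = None,
                             benchmark: CropBenchmark | None = None) -> RunReport:
    """Train baseline + VIB per seed and evaluate the six manipulation cases."""
    if config is None:
        config = ClassificationStudyConfig()
    if seeds is None:
        seeds = list(range(8))
    if len(seeds) < 5:
        raise ValueError("classification study needs >= 5 seeds")
    if benchmark is None:
        benchmark = build_crop_benchmark(config)

    rows = []
    acc: dict[tuple[int, int], float] = {}  # (case, seed) -> accuracy
    for seed in seeds:
        models = {
            "baseline": vib.train_classifier(benchmark.train_crops,
                                             benchmark.train_labels,
                                             config.baseline, seed=seed),
            "vib": vib.train_classifier(benchmark.train_crops,
                                        benchmark.train_labels,
                                        config.vib, seed=seed),
        }
        for case, (model_name, neg_v, pos_v) in CASE_SPECS.items():
            a = _case_accuracy(models[model_name], benchmark, neg_v, pos_v)
            acc[(case, seed)] = a
            rows.append({"case": case, "model": model_name, "negative": neg_v,
                         "positive": pos_v, "seed": seed, "accuracy": 100 * a})

    def series(case):
        return np.array([acc[(case, s)] for s in seeds]) * 100

    summary = {f"case{c}": {"mean": float(series(c).mean()),
                            "sd": float(series(c).std(ddof=1)),
                            "per_seed": series(c).tolist()}
               for c in CASE_SPECS}
    c1, c2, c3 = series(1), series(2), series(3)
    c4, c6 = series(4), series(6)
    n = len(seeds)
    base_drop = float(c1.mean() - c3.mean())
    vib_drop = float(c4.mean() - c6.mean())
    ordering = {
        "case1_gt_case2_count": int((c1 > c2).sum()),
        "case1_gt_case2_p": sign_test(int((c1 > c2).sum()), n),
        "case2_gt_case3_count": int((c2 > c3).sum()),
        "case2_gt_case3_p": sign_test(int((c2 > c3).sum()), n),
        "baseline_drop_mean": base_drop,
        "vib_drop_mean": vib_drop,
        "vib_drop_abs_lt_baseline_drop_abs": bool(abs(vib_drop) < abs(base_drop)),
    }
    return RunReport(rows=rows, summary=summary, ordering=ordering,
                     seeds=list(seeds),
                     config_hash=_config_hash({"cls": config.baseline,
                                               "vib": config.vib,
                                               "bench_seed": config.benchmark_seed}))
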