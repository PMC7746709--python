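"""Readers/writers for on-disk formats and the pipeline orchestrator.

Formats are deliberately plain: contours as two-column x,y CSV, profiles and
responses as flat CSV, segmentations and correspondences as JSON, run
configuration as YAML.  Arc positions are always serialized as fractions of
perimeter in [0, 1), never pixels, so files are scale invariant.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .contour import (
    ClosedContour,
    InvalidContourError,
    SurprisalProfile,
    resample_equidistant,
    surprisal_profile,
    turning_angle_profile,
)
from .metrics import (
    ResponseTable,
    compare_model,
    congruity,
    model_congruity,
    median_responses,
    ordering_preservation,
)
from .models import (
    align_start_to_leftmost_part,
    combined_predict,
    curvature_predict,
    detect_landmarks,
    dtw_align,
    _profile_values_for_heading,
    uniform_predict,
)
from .parts import (
    CorrespondencePrediction,
    Heading,
    LabelCorrespondence,
    PartSegmentation,
    infer_heading,
    semantic_predict,
)

logger = logging.getLogger(__name__)

MODEL_IDS = ("semantic", "uniform", "curvature", "combined")


# ---------------------------------------------------------------------------
# contours


def load_contour_csv(path) -> ClosedContour:
    """Contour from a two-float-column CSV ('#' comments allowed)."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = re.split(r"[,\s;]+", line)
        if parts and parts[0].lower() in ("x", "x,y"):
            continue
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed vertex row {line!r}") from exc
    if len(rows) < 3:
        raise InvalidContourError(f"{path}: fewer than 3 vertices")
    return ClosedContour(np.array(rows))


def save_contour_csv(contour: ClosedContour, path, header: str = "") -> None:
    lines = [f"# {h}" for h in header.splitlines() if h] + ["x,y"]
    lines += [f"{x:.12g},{y:.12g}" for x, y in contour.vertices]
    Path(path).write_text("\n".join(lines) + "\n")


# --- minimal SVG path import ------------------------------------------------

_TOKEN = re.compile(r"([MmLlHhVvCcSsQqTtAaZz])|(-?\d*\.?\d+(?:[eE][-+]?\d+)?)")


def _parse_path_data(d: str):
    """SVG path data -> list of absolute cubic/linear primitives."""
    tokens = [(m.group(1), m.group(2)) for m in _TOKEN.finditer(d)]
    i, cmd = 0, None
    cur = np.zeros(2)
    start = None
    prev_ctrl = None
    segs = []  # ("line", p0, p1) | ("cubic", p0, c1, c2, p1) | ("arc", ...)

    def read(n):
        nonlocal i
        vals = []
        for _ in range(n):
            vals.append(float(tokens[i][1]))
            i += 1
        return vals

    while i < len(tokens):
        if tokens[i][0] is not None:
            cmd = tokens[i][0]
            i += 1
        c = cmd
        rel = c.islower()
        C = c.upper()
        if C == "M":
            x, y = read(2)
            cur = cur + [x, y] if rel else np.array([x, y])
            start = cur.copy()
            cmd = "l" if rel else "L"
        elif C == "L":
            x, y = read(2)
            nxt = cur + [x, y] if rel else np.array([x, y])
            segs.append(("line", cur.copy(), nxt))
            cur = nxt
        elif C == "H":
            (x,) = read(1)
            nxt = np.array([cur[0] + x if rel else x, cur[1]])
            segs.append(("line", cur.copy(), nxt))
            cur = nxt
        elif C == "V":
            (y,) = read(1)
            nxt = np.array([cur[0], cur[1] + y if rel else y])
            segs.append(("line", cur.copy(), nxt))
            cur = nxt
        elif C in "CS":
            if C == "C":
                x1, y1, x2, y2, x, y = read(6)
                c1 = cur + [x1, y1] if rel else np.array([x1, y1])
            else:
                x2, y2, x, y = read(4)
                c1 = 2 * cur - prev_ctrl if prev_ctrl is not None else cur.copy()
            c2 = cur + [x2, y2] if rel else np.array([x2, y2])
            nxt = cur + [x, y] if rel else np.array([x, y])
            segs.append(("cubic", cur.copy(), c1, c2, nxt))
            prev_ctrl = c2
            cur = nxt
            continue
        elif C in "QT":
            if C == "Q":
                x1, y1, x, y = read(4)
                q = cur + [x1, y1] if rel else np.array([x1, y1])
            else:
                (x, y) = read(2)
                q = 2 * cur - prev_ctrl if prev_ctrl is not None else cur.copy()
            nxt = cur + [x, y] if rel else np.array([x, y])
            # exact quadratic -> cubic elevation
            c1 = cur + 2.0 / 3.0 * (q - cur)
            c2 = nxt + 2.0 / 3.0 * (q - nxt)
            segs.append(("cubic", cur.copy(), c1, c2, nxt))
            prev_ctrl = q
            cur = nxt
            continue
        elif C == "A":
            rx, ry, rot, laf, sf, x, y = read(7)
            nxt = cur + [x, y] if rel else np.array([x, y])
            segs.append(("arc", cur.copy(), rx, ry, np.radians(rot), laf, sf, nxt))
            cur = nxt
        elif C == "Z":
            if start is not None and not np.allclose(cur, start):
                segs.append(("line", cur.copy(), start.copy()))
            cur = start.copy() if start is not None else cur
            return segs  # first closed subpath only
        prev_ctrl = None
    return segs


def _flatten_segment(seg, tol: float):
    kind = seg[0]
    if kind == "line":
        return [seg[1], seg[2]]
    if kind == "cubic":
        p0, c1, c2, p1 = seg[1:]
        chord = np.linalg.norm(p1 - p0)
        # chord-error bound for cubics via control-polygon distance
        dev = max(np.linalg.norm(c1 - p0), np.linalg.norm(c2 - p1), 1e-12)
        n = max(2, int(np.ceil(np.sqrt(dev / max(tol, 1e-9)) * 4)), int(chord / max(tol, 1e-9)) ** 0 * 2)
        n = min(max(n, 8), 512)
        t = np.linspace(0, 1, n + 1)[:, None]
        pts = ((1 - t) ** 3 * p0 + 3 * (1 - t) ** 2 * t * c1
               + 3 * (1 - t) * t ** 2 * c2 + t ** 3 * p1)
        return list(pts)
    if kind == "arc":
        p0, rx, ry, rot, laf, sf, p1 = seg[1:]
        return _flatten_arc(p0, rx, ry, rot, laf, sf, p1, tol)
    raise ValueError(kind)  # pragma: no cover


def _flatten_arc(p0, rx, ry, rot, large_arc, sweep, p1, tol):
    """Endpoint -> centre parameterization (SVG spec appendix) + sampling."""
    if rx == 0 or ry == 0 or np.allclose(p0, p1):
        return [p0, p1]
    rx, ry = abs(rx), abs(ry)
    cosr, sinr = np.cos(rot), np.sin(rot)
    R = np.array([[cosr, sinr], [-sinr, cosr]])
    p = R @ ((p0 - p1) / 2)
    lam = (p[0] / rx) ** 2 + (p[1] / ry) ** 2
    if lam > 1:
        s = np.sqrt(lam)
        rx, ry = rx * s, ry * s
    num = rx**2 * ry**2 - rx**2 * p[1] ** 2 - ry**2 * p[0] ** 2
    den = rx**2 * p[1] ** 2 + ry**2 * p[0] ** 2
    coef = np.sqrt(max(num / den, 0.0))
    if large_arc == sweep:
        coef = -coef
    cp = coef * np.array([rx * p[1] / ry, -ry * p[0] / rx])
    centre = R.T @ cp + (p0 + p1) / 2
    v1 = np.array([(p[0] - cp[0]) / rx, (p[1] - cp[1]) / ry])
    v2 = np.array([(-p[0] - cp[0]) / rx, (-p[1] - cp[1]) / ry])
    th1 = np.arctan2(v1[1], v1[0])
    dth = np.arctan2(v1[0] * v2[1] - v1[1] * v2[0], v1 @ v2)
    if not sweep and dth > 0:
        dth -= 2 * np.pi
    if sweep and dth < 0:
        dth += 2 * np.pi
    r_eff = max(rx, ry)
    n = max(4, int(np.ceil(abs(dth) / (2 * np.arccos(max(1 - tol / r_eff, -1.0))))))
    n = min(n, 1024)
    th = th1 + dth * np.linspace(0, 1, n + 1)
    pts = (R.T @ np.vstack([rx * np.cos(th), ry * np.sin(th)])).T + centre
    return list(pts)


def load_contour_svg(path, tol: float = 0.01) -> ClosedContour:
    """First closed path of an SVG, flattened at chord-error tolerance ``tol``."""
    text = Path(path).read_text()
    m = re.search(r'\bd\s*=\s*"([^"]+)"', text) or re.search(r"\bd\s*=\s*'([^']+)'", text)
    if not m:
        raise ValueError(f"{path}: no path data found")
    segs = _parse_path_data(m.group(1))
    if not segs:
        raise InvalidContourError(f"{path}: path has no segments")
    pts = []
    for seg in segs:
        flat = _flatten_segment(seg, tol)
        pts.extend(flat[:-1])
    arr = np.array(pts)
    keep = np.ones(len(arr), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(arr, axis=0), axis=1) > 1e-12
    return ClosedContour(arr[keep])


def load_contour(path, fmt: str | None = None) -> ClosedContour:
    fmt = fmt or ("svg" if str(path).lower().endswith(".svg") else "csv")
    if fmt == "svg":
        return load_contour_svg(path)
    return load_contour_csv(path)


# ---------------------------------------------------------------------------
# profiles, segmentations, correspondences, responses, predictions


def save_profile_csv(profile: SurprisalProfile, path) -> None:
    df = pd.DataFrame(
        {
            "s": profile.positions,
            "theta": profile.theta,
            "u_raw": profile.u_raw,
            "u_norm": profile.u_norm,
            "u_signed": profile.u_signed,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# kappa={profile.kappa}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def save_segmentation_json(seg: PartSegmentation, path) -> None:
    data = [
        {"label": lab, "s_start": float(a), "s_end": float(b)}
        for lab, a, b in seg.segments
    ]
    Path(path).write_text(json.dumps(data, indent=1) + "\n")


def load_segmentation_json(path) -> PartSegmentation:
    data = json.loads(Path(path).read_text())
    return PartSegmentation([(d["label"], d["s_start"], d["s_end"]) for d in data])


def save_correspondence_json(corr: LabelCorrespondence, path) -> None:
    data = [
        {"base_labels": list(bl), "test_labels": list(tl)} for bl, tl in corr.groups
    ]
    Path(path).write_text(json.dumps(data, indent=1) + "\n")


def load_correspondence_json(path) -> LabelCorrespondence:
    data = json.loads(Path(path).read_text())
    return LabelCorrespondence(
        [(tuple(d["base_labels"]), tuple(d["test_labels"])) for d in data]
    )


def save_responses_csv(table: ResponseTable, path) -> None:
    rows = []
    for i, s in enumerate(table.probes):
        for j, part in enumerate(table.participants):
            rows.append(
                {
                    "pair_id": table.pair_id,
                    "participant": part,
                    "probe_index": i,
                    "probe_s": s,
                    "response_s": table.responses[i, j],
                    "group": table.groups.get(part, ""),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def load_responses_csv(path, pair_id: str | None = None) -> ResponseTable:
    df = pd.read_csv(path)
    if pair_id is not None:
        df = df[df["pair_id"] == pair_id]
    if df.empty:
        raise ValueError(f"{path}: no responses" + (f" for {pair_id}" if pair_id else ""))
    pid = str(df["pair_id"].iloc[0])
    wide = df.pivot_table(index="probe_index", columns="participant",
                          values="response_s", sort=True)
    probes = df.drop_duplicates("probe_index").sort_values("probe_index")["probe_s"].to_numpy()
    groups = {}
    if "group" in df.columns:
        for part, g in df.drop_duplicates("participant")[["participant", "group"]].itertuples(index=False):
            if isinstance(g, str) and g:
                groups[part] = g
    return ResponseTable(pid, probes, wide.to_numpy(), list(wide.columns), groups)


def save_predictions_csv(predictions: dict, path, pair_id: str) -> None:
    """``predictions``: model_id -> list of CorrespondencePrediction."""
    rows = []
    for model_id, preds in predictions.items():
        for i, p in enumerate(preds):
            rows.append(
                {
                    "pair_id": pair_id,
                    "model": model_id,
                    "probe_index": i,
                    "probe_s": p.probe,
                    "predicted_s": p.predicted,
                    "valid": bool(p.valid),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def load_votes_csv(path):
    """Label-votes long CSV -> LabelVotes."""
    from .parts import LabelVotes, PART_VOCABULARY

    df = pd.read_csv(path)
    points = np.sort(df["point_index"].unique())
    extra = [l for l in df["label"].unique() if l not in PART_VOCABULARY]
    vocab = tuple(PART_VOCABULARY) + tuple(sorted(extra))
    counts = np.zeros((points.size, len(vocab)), dtype=int)
    positions = np.zeros(points.size)
    for k, pi in enumerate(points):
        sub = df[df["point_index"] == pi]
        positions[k] = sub["s"].iloc[0]
        for lab, c in sub["label"].value_counts().items():
            counts[k, vocab.index(lab)] += int(c)
    return LabelVotes(positions, vocab, counts, int(df["participant"].nunique()))


def save_votes_csv(votes, path, pair_id: str = "") -> None:
    rows = []
    for i in range(votes.counts.shape[0]):
        emitted = 0
        for j, lab in enumerate(votes.labels):
            for _ in range(int(votes.counts[i, j])):
                rows.append(
                    {
                        "point_index": i,
                        "s": votes.positions[i],
                        "participant": f"l{emitted:02d}",
                        "label": lab,
                    }
                )
                emitted += 1
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# prediction driver shared by CLI, scripts and tests


def predict_all_models(
    base: ClosedContour,
    base_seg: PartSegmentation,
    test: ClosedContour,
    test_seg: PartSegmentation,
    corr: LabelCorrespondence,
    heading: Heading | None = None,
    n_probes: int = 50,
    probes=None,
    kappa: float = 1.0,
    window_w: float = 0.05,
    m_profile: int = 200,
    models=MODEL_IDS,
) -> dict:
    """Per-model correspondence predictions for one shape pair.

    Returns ``{model_id: [CorrespondencePrediction, ...]}`` over ``probes``
    (default: ``n_probes`` equidistant positions from the base reference
    start).  Heading defaults to the direction inferred from part order.
    """
    if heading is None:
        heading = infer_heading(base_seg, test_seg, corr)
    if probes is None:
        probes, _ = resample_equidistant(base, n_probes)
    probes = np.mod(np.asarray(probes, dtype=float), 1.0)
    n = probes.size
    out: dict = {}
    if "semantic" in models or "combined" in models:
        sem = [semantic_predict(s, base_seg, test_seg, corr, heading) for s in probes]
        if "semantic" in models:
            out["semantic"] = sem
    needs_profiles = "curvature" in models or "combined" in models
    start_base = start_test = 0.0
    if "uniform" in models or needs_profiles:
        start_base = align_start_to_leftmost_part(base, base_seg)
        start_test = align_start_to_leftmost_part(test, test_seg)
    if "uniform" in models:
        # the i-th probe keeps its offset from the aligned start; the
        # prediction reproduces that offset on the test contour
        out["uniform"] = []
        for i in range(n):
            p = uniform_predict(i, n, start_base, start_test, heading)
            p.probe = float(probes[i])
            p.predicted = float(
                (start_test + heading.sign * ((probes[i] - start_base) % 1.0)) % 1.0
            )
            out["uniform"].append(p)
    if needs_profiles:
        prof_base = surprisal_profile(
            turning_angle_profile(base, m_profile, window_w, start=start_base), kappa
        )
        prof_test = surprisal_profile(
            turning_angle_profile(test, m_profile, window_w, start=start_test), kappa
        )
        if "curvature" in models:
            u_t = _profile_values_for_heading(prof_test, heading)
            path = dtw_align(prof_base.u_norm, u_t)
            out["curvature"] = [
                curvature_predict(s, path, m_profile, m_profile,
                                  start_base, start_test, heading)
                for s in probes
            ]
        if "combined" in models:
            prof_base_abs = surprisal_profile(
                turning_angle_profile(base, m_profile, window_w), kappa
            )
            prof_test_abs = surprisal_profile(
                turning_angle_profile(test, m_profile, window_w), kappa
            )
            lm_base = detect_landmarks(prof_base_abs)
            lm_test = detect_landmarks(prof_test_abs)
            out["combined"] = [
                combined_predict(s, base_seg, test_seg, corr, heading, lm_base, lm_test)
                for s in probes
            ]
    return out


# ---------------------------------------------------------------------------
# run configuration and pipeline


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run."""

    out_dir: str = "results/run"
    preset: str = "exp1"
    seed: int = 0
    n_probes: int = 50
    n_participants: int = 15
    kappa: float = 1.0
    window_w: float = 0.05
    m_profile: int = 200
    bf_scale: float = 0.707
    kappa_resp: float = 625.0
    reversal_prob: float = 0.0
    lapse_rate: float = 0.0
    heading_policy: str = "auto"   # auto | same | reversed
    models: tuple = MODEL_IDS
    morph_levels: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: v for k, v in data.items() if k in cls.__dataclass_fields__})
        cfg.models = tuple(cfg.models)
        cfg.morph_levels = tuple(cfg.morph_levels)
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> label -> predict -> evaluate for a synthetic preset.

    Writes contour CSVs, segmentation JSON, response/prediction CSVs and a
    per-pair results JSON under ``config.out_dir``; re-running with the same
    config reproduces identical outputs.  Returns the results dict.
    """
    from .synthetic import ObserverSpec, exp1_battery, exp2_battery, simulate_responses

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    chash = config.config_hash()
    if config.preset == "exp1":
        pairs = exp1_battery(config.seed)
    elif config.preset == "exp2":
        pairs = exp2_battery(config.seed)
    else:
        raise ValueError(f"unknown preset: {config.preset}")

    results = {"config_hash": chash, "seed": config.seed, "pairs": {}}
    for k, pair in enumerate(pairs):
        obs = ObserverSpec(
            n_participants=config.n_participants,
            kappa_resp=config.kappa_resp,
            reversal_prob=config.reversal_prob,
            lapse_rate=config.lapse_rate,
            seed=config.seed * 1009 + k,
        )
        probes, _ = resample_equidistant(pair.base, config.n_probes)
        table = simulate_responses(pair, obs, probes=probes)
        heading = None if config.heading_policy == "auto" else Heading(config.heading_policy)
        preds = predict_all_models(
            pair.base, pair.base_seg, pair.test, pair.test_seg, pair.corr,
            heading=heading if heading else pair.heading,
            probes=probes, kappa=config.kappa, window_w=config.window_w,
            m_profile=config.m_profile, models=config.models,
        )
        save_contour_csv(pair.base, out / f"{pair.pair_id}_base.csv",
                         header=f"config={chash} seed={config.seed}")
        save_contour_csv(pair.test, out / f"{pair.pair_id}_test.csv",
                         header=f"config={chash} seed={config.seed}")
        save_segmentation_json(pair.base_seg, out / f"{pair.pair_id}_base_seg.json")
        save_segmentation_json(pair.test_seg, out / f"{pair.pair_id}_test_seg.json")
        save_responses_csv(table, out / f"{pair.pair_id}_responses.csv")
        save_predictions_csv(preds, out / f"{pair.pair_id}_predictions.csv", pair.pair_id)

        cong = congruity(table)
        med = median_responses(table)
        preserved, reversals = ordering_preservation(
            med, "reversed" if pair.heading.direction == "reversed" else "same"
        )
        pair_res = {
            "congruity": cong.congruity,
            "preserved_percent": preserved,
            "order_reversals": int(reversals),
            "models": {},
            "config_hash": chash,
            "seed": obs.seed,
        }
        for model_id, plist in preds.items():
            cmp_res = compare_model(table, plist, bf_scale=config.bf_scale)
            mc = model_congruity(
                np.array([p.predicted if p.valid else np.nan for p in plist]), table
            )
            pair_res["models"][model_id] = {
                "mean_distance": float(np.mean(cmp_res.model_distance)),
                "human_distance": float(np.mean(cmp_res.human_distance)),
                "congruity": mc.congruity,
                "t": cmp_res.t,
                "df": cmp_res.df,
                "p": cmp_res.p,
                "BF10": cmp_res.bf10,
            }
        results["pairs"][pair.pair_id] = pair_res
    (out / "results.json").write_text(json.dumps(results, indent=1, sort_keys=True) + "\n")
    return results


# ---------------------------------------------------------------------------
# deposited-archive adapter


def load_archive_pair(archive_dir, pair_id: str):
    """Load one shape pair from a local copy of the deposited study archive.

    Expects, under ``archive_dir``: ``<pair>_base.csv`` / ``<pair>_test.csv``
    contours, ``<pair>_base_seg.json`` / ``<pair>_test_seg.json``
    segmentations, ``<pair>_corr.json`` label correspondence and
    ``<pair>_responses.csv`` dot-matching responses (the formats this
    package writes).  A thin mapping layer for whatever layout the archive
    actually uses can convert into these files once inspected.
    """
    d = Path(archive_dir)
    if not d.exists():
        raise FileNotFoundError(f"archive directory {d} not found")
    base = load_contour(d / f"{pair_id}_base.csv")
    test = load_contour(d / f"{pair_id}_test.csv")
    base_seg = load_segmentation_json(d / f"{pair_id}_base_seg.json")
    test_seg = load_segmentation_json(d / f"{pair_id}_test_seg.json")
    corr = load_correspondence_json(d / f"{pair_id}_corr.json")
    table = load_responses_csv(d / f"{pair_id}_responses.csv", pair_id)
    return base, base_seg, test, test_seg, corr, table
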