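"""SIFT-based near-duplicate detection and label-conflict auditing.

Public ultrasound collections contain zoomed/rotated copies of the same
acquisition, sometimes filed under different labels; training and evaluating
on both copies inflates accuracy.  Pairs are compared with scale-invariant
keypoints: SIFT descriptors, a nearest-neighbor ratio test, and geometric
verification under a similarity transform (rotation + scale + translation —
exactly the transform class of a zoomed/rotated copy).  A pair is a
duplicate when enough matches survive verification; duplicate clusters are
the connected components of the pairwise graph.

Known limitation, reproduced deliberately: different frames of the *same*
nodule over time (same anatomy, different speckle realization) share no
keypoints and are NOT detected — such frames need manual review.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import SIFT, match_descriptors
from skimage.measure import ransac
from skimage.transform import SimilarityTransform

from .errors import InputError
from .phantom import load_image

DEFAULT_RATIO = 0.75
DEFAULT_MIN_INLIERS = 25


@dataclass
class MatchEvidence:
    keypoints_a: int
    keypoints_b: int
    matches: int
    inliers: int


@dataclass
class DuplicateCluster:
    """Connected component of near-identical images."""

    members: list[str]
    evidence: dict[tuple[str, str], MatchEvidence] = field(default_factory=dict)
    labels: dict[str, bool] = field(default_factory=dict)
    representative: str | None = None

    @property
    def conflict(self) -> bool:
        return len(set(self.labels.values())) > 1


def _extract(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sift = SIFT()
    try:
        sift.detect_and_extract(img.astype(np.float64) / 255.0)
    except RuntimeError:  # no keypoints found
        return np.empty((0, 2)), np.empty((0, 128), dtype=np.uint8)
    return sift.keypoints, sift.descriptors


def match_pair(img_a: np.ndarray, img_b: np.ndarray,
               ratio: float = DEFAULT_RATIO,
               min_inliers: int = DEFAULT_MIN_INLIERS,
               _features=None) -> tuple[bool, MatchEvidence]:
    """Decide whether two grayscale images are near-duplicates.

    Symmetric in its arguments.  Featureless images yield not-duplicate with
    zero evidence rather than an error.
    """
    if _features is not None:
        (kp_a, des_a), (kp_b, des_b) = _features
    else:
        kp_a, des_a = _extract(np.asarray(img_a))
        kp_b, des_b = _extract(np.asarray(img_b))
    ev = MatchEvidence(len(kp_a), len(kp_b), 0, 0)
    if len(kp_a) < 2 or len(kp_b) < 2:
        return False, ev
    pairs = match_descriptors(des_a, des_b, max_ratio=ratio, cross_check=True)
    ev.matches = len(pairs)
    if len(pairs) < max(3, min_inliers // 4):
        return False, ev
    src = kp_a[pairs[:, 0]][:, ::-1]  # (row, col) -> (x, y)
    dst = kp_b[pairs[:, 1]][:, ::-1]
    try:
        _, inliers = ransac((src, dst), SimilarityTransform, min_samples=3,
                            residual_threshold=4.0, max_trials=300,
                            rng=np.random.default_rng(0))
    except ValueError:
        inliers = None
    ev.inliers = 0 if inliers is None else int(inliers.sum())
    return ev.inliers >= min_inliers, ev


def find_duplicates(manifest: dict, ratio: float = DEFAULT_RATIO,
                    min_inliers: int = DEFAULT_MIN_INLIERS
                    ) -> list[DuplicateCluster]:
    """Cluster the manifest's images by the pairwise duplicate graph.

    SIFT features are extracted once per image; clusters are connected
    components, so chains (a~b, b~c) merge into one cluster.  Images outside
    every cluster are unique.
    """
    records = manifest["records"]
    if len(records) < 2:
        raise InputError("need at least 2 images to search for duplicates")
    ids = [r["image_id"] for r in records]
    feats = {r["image_id"]: _extract(load_image(manifest, r)) for r in records}
    labels = {r["image_id"]: bool(r["malignant"]) for r in records}

    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    evidence: dict[tuple[str, str], MatchEvidence] = {}
    for i, id_a in enumerate(ids):
        for id_b in ids[i + 1:]:
            dup, ev = match_pair(None, None, ratio, min_inliers,
                                 _features=(feats[id_a], feats[id_b]))
            if dup:
                evidence[(id_a, id_b)] = ev
                parent[find(id_a)] = find(id_b)

    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    clusters = []
    for members in groups.values():
        if len(members) < 2:
            continue
        members = sorted(members)
        cluster = DuplicateCluster(
            members=members,
            evidence={k: v for k, v in evidence.items()
                      if k[0] in members and k[1] in members},
            labels={m: labels[m] for m in members},
            representative=members[0],
        )
        clusters.append(cluster)
    return sorted(clusters, key=lambda c: c.members[0])


def conflict_report(clusters: list[DuplicateCluster],
                    labels: dict[str, bool],
                    drop_conflicted: bool = True) -> dict:
    """Audit clusters against malignancy labels and count removals.

    Policy: keep one representative per clean cluster (removing the rest);
    clusters whose members disagree on the label are flagged and — under the
    default drop-conflicted policy — removed entirely.
    """
    rows = []
    n_removed = 0
    for idx, cluster in enumerate(clusters):
        missing = [m for m in cluster.members if m not in labels]
        if missing:
            raise InputError(f"labels missing for {missing}")
        lab = {m: bool(labels[m]) for m in cluster.members}
        conflict = len(set(lab.values())) > 1
        if conflict and drop_conflicted:
            action = "drop_all"
            removed = list(cluster.members)
        else:
            action = "keep_representative"
            removed = [m for m in cluster.members if m != cluster.representative]
        n_removed += len(removed)
        rows.append({
            "cluster_id": idx,
            "members": list(cluster.members),
            "labels": lab,
            "conflict": conflict,
            "representative": cluster.representative,
            "action": action,
            "removed": removed,
        })
    return {
        "clusters": rows,
        "n_clusters": len(rows),
        "n_conflicted": sum(r["conflict"] for r in rows),
        "n_images_removed": n_removed,
    }


def report_to_csv(report: dict, path) -> None:
    import pandas as pd

    rows = [{
        "cluster_id": r["cluster_id"],
        "members": ";".join(r["members"]),
        "labels": ";".join(str(r["labels"][m]) for m in r["members"]),
        "conflict": r["conflict"],
        "action": r["action"],
        "removed": ";".join(r["removed"]),
    } for r in report["clusters"]]
    pd.DataFrame(rows, columns=["cluster_id", "members", "labels", "conflict",
                                "action", "removed"]).to_csv(path, index=False)
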