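"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use plain Python loops and textbook formulas, sharing no
code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def glcm_oracle(band, mask, levels, offsets):
    """Object-level GLCM statistics by explicit pair enumeration.

    For every offset (dr, dc) and every mask pixel (r, c), the pair
    ((r, c), (r+dr, c+dc)) is counted iff the neighbour is also a mask
    pixel; counts are symmetrized, pooled over offsets, normalized; the
    seven statistics are computed with explicit double loops.
    """
    band = np.asarray(band, dtype=float)
    h, w = band.shape
    bin_width = 256.0 / levels
    mask_set = {(int(r), int(c)) for r, c in mask}
    counts = [[0 for _ in range(levels)] for _ in range(levels)]
    total = 0
    for r, c in sorted(mask_set):
        for dr, dc in offsets:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and (nr, nc) in mask_set:
                i = min(int(band[r, c] // bin_width), levels - 1)
                j = min(int(band[nr, nc] // bin_width), levels - 1)
                counts[i][j] += 1
                counts[j][i] += 1
                total += 2
    if total == 0:
        return None
    p = [[counts[i][j] / total for j in range(levels)] for i in range(levels)]
    p_i = [sum(p[i][j] for j in range(levels)) for i in range(levels)]
    mu = sum(i * p_i[i] for i in range(levels))
    var = sum((i - mu) ** 2 * p_i[i] for i in range(levels))
    contrast = dissimilarity = homogeneity = entropy = second_moment = 0.0
    variance = corr_num = 0.0
    for i in range(levels):
        for j in range(levels):
            pij = p[i][j]
            if pij == 0:
                continue
            contrast += pij * (i - j) ** 2
            dissimilarity += pij * abs(i - j)
            homogeneity += pij / (1 + (i - j) ** 2)
            entropy -= pij * math.log(pij)
            second_moment += pij * pij
            variance += pij * (i - mu) ** 2
            corr_num += pij * (i - mu) * (j - mu)
    correlation = corr_num / var if var > 0 else 0.0
    return {
        "variance": variance,
        "homogeneity": homogeneity,
        "contrast": contrast,
        "dissimilarity": dissimilarity,
        "entropy": entropy,
        "second_moment": second_moment,
        "correlation": correlation,
    }


def nearest_centroid_accuracy(features, labels):
    """Accuracy of labelling each row by its nearest class centroid."""
    features = np.asarray(features, dtype=float)
    labels = list(labels)
    classes = sorted(set(labels))
    centroids = {
        cls: features[[i for i, l in enumerate(labels) if l == cls]].mean(axis=0)
        for cls in classes
    }
    hits = 0
    for row, truth in zip(features, labels):
        best = min(classes, key=lambda cls: float(np.linalg.norm(row - centroids[cls])))
        hits += best == truth
    return hits / len(labels)
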