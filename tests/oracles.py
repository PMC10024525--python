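"""Independent brute-force reference implementations used only by tests."""

from __future__ import annotations

import math


def brute_class_areas(values, nodata, row_areas, select=None):
    """Per-class area by an explicit per-pixel python loop."""
    out: dict[int, float] = {}
    n_rows = len(values)
    for r in range(n_rows):
        for c in range(len(values[r])):
            if select is not None and not select[r][c]:
                continue
            v = int(values[r][c])
            if v == nodata:
                continue
            out[v] = out.get(v, 0.0) + row_areas[r]
    return out


def brute_transition(values_a, values_b, nodata, row_areas, select=None):
    """(from, to) → area by an explicit double per-pixel loop."""
    out: dict[tuple[int, int], float] = {}
    for r in range(len(values_a)):
        for c in range(len(values_a[r])):
            if select is not None and not select[r][c]:
                continue
            a = int(values_a[r][c])
            b = int(values_b[r][c])
            if a == nodata or b == nodata:
                continue
            out[(a, b)] = out.get((a, b), 0.0) + row_areas[r]
    return out


def brute_zonal_mean(scores, row_areas, select=None):
    """(area-weighted mean, total) over finite pixels by a python loop."""
    total = 0.0
    weight = 0.0
    for r in range(len(scores)):
        for c in range(len(scores[r])):
            if select is not None and not select[r][c]:
                continue
            v = float(scores[r][c])
            if math.isnan(v):
                continue
            total += v * row_areas[r]
            weight += row_areas[r]
    mean = total / weight if weight > 0 else float("nan")
    return mean, total


def brute_consensus(studies):
    """(service, class) → (min, mean, max) over the studies reporting it."""
    pooled: dict[tuple, list[float]] = {}
    for study in studies:
        for key, score in study.scores.items():
            pooled.setdefault(key, []).append(score)
    return {
        key: (min(v), sum(v) / len(v), max(v)) for key, v in pooled.items()
    }
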