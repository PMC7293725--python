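"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (explicit
loops, exhaustive enumeration, unit tracking) and must stay independent
of the library code paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata


def flood_fill_label(mask: np.ndarray) -> np.ndarray:
    """8-connected component labelling by explicit stack-based flood fill.

    Labels are assigned in raster-scan order of each component's first
    pixel, starting at 1.
    """
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    nxt = 0
    for sr in range(h):
        for sc in range(w):
            if not mask[sr, sc] or labels[sr, sc]:
                continue
            nxt += 1
            stack = [(sr, sc)]
            labels[sr, sc] = nxt
            while stack:
                r, c = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < h
                            and 0 <= cc < w
                            and mask[rr, cc]
                            and not labels[rr, cc]
                        ):
                            labels[rr, cc] = nxt
                            stack.append((rr, cc))
    return labels


def crack_perimeter_loop(mask: np.ndarray) -> int:
    """Perimeter by counting exposed 4-neighbour edges, pixel by pixel."""
    h, w = mask.shape
    per = 0
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                    per += 1
    return per


def background_from_border(gray: np.ndarray, cutoff: float) -> np.ndarray:
    """Bright pixels 8-connected to the image border, by flood fill."""
    bright = gray > cutoff
    labels = flood_fill_label(bright)
    h, w = gray.shape
    border_ids = set()
    for r in range(h):
        for c in (0, w - 1):
            if labels[r, c]:
                border_ids.add(labels[r, c])
    for c in range(w):
        for r in (0, h - 1):
            if labels[r, c]:
                border_ids.add(labels[r, c])
    out = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            if labels[r, c] in border_ids:
                out[r, c] = True
    return out


def touches_tissue_border(region: np.ndarray, tissue: np.ndarray) -> bool:
    """True if any region pixel is 8-adjacent to non-tissue or the image edge."""
    h, w = tissue.shape
    for r in range(h):
        for c in range(w):
            if not region[r, c]:
                continue
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w):
                        return True
                    if not tissue[rr, cc]:
                        return True
    return False


def brute_quantify(
    gray: np.ndarray,
    threshold: float,
    *,
    tissue_white_cutoff: float,
    min_vacuole_px: int,
    max_vacuole_px: int,
    min_circularity: float,
    exclude_border_regions: bool,
):
    """Full brute-force quantification (solidity rule disabled).

    Returns (tissue, labels, regions, steatosis_pct) where regions maps
    label -> (area, classification).
    """
    background = background_from_border(gray, tissue_white_cutoff)
    tissue = ~background
    candidate = tissue & (gray > threshold)
    labels = flood_fill_label(candidate)
    regions: dict[int, tuple[int, str]] = {}
    fat_area = 0
    for lbl in range(1, labels.max() + 1):
        region = labels == lbl
        area = int(region.sum())
        if area < min_vacuole_px:
            continue
        per = crack_perimeter_loop(region)
        circ = 4.0 * np.pi * area / per**2
        if area > max_vacuole_px:
            cls = "excluded_large"
        elif circ < min_circularity:
            cls = "excluded_shape"
        elif exclude_border_regions and touches_tissue_border(region, tissue):
            cls = "excluded_border"
        else:
            cls = "fat"
            fat_area += area
        regions[lbl] = (area, cls)
    tissue_area = int(tissue.sum())
    return tissue, labels, regions, 100.0 * fat_area / tissue_area


def wilcoxon_exact_two_sided(d) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns.

    Zeros dropped, average ranks for tied magnitudes;
    p = min(1, 2 * min(P(W <= w), P(W >= w))) under the symmetric null.
    """
    d = np.asarray(d, dtype=float)
    nz = d[d != 0]
    n = nz.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(nz))
    w_obs = ranks[nz > 0].sum()
    ws = np.array(
        [np.dot(signs, ranks) for signs in itertools.product((0, 1), repeat=n)]
    )
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def carbonyl_by_unit_tracking(
    absorbance: float,
    blank: float,
    epsilon_M_cm: float,
    path_cm: float,
    protein_mg_ml: float,
    dilution: float,
) -> float:
    """Dimensional-analysis recomputation of carbonyl content.

    A [1] / (eps [L mol^-1 cm^-1] * l [cm])     -> c   [mol L^-1]
    c * 1e9 [nmol mol^-1]                       -> c   [nmol L^-1]
    / 1e3 [mL L^-1]                             -> c   [nmol mL^-1]
    / protein [mg mL^-1] * dilution             -> nmol mg^-1
    """
    net = absorbance - blank
    mol_per_L = net / epsilon_M_cm / path_cm
    nmol_per_L = mol_per_L * 1.0e9
    nmol_per_mL = nmol_per_L / 1.0e3
    return nmol_per_mL / protein_mg_ml * dilution


def ols_normal_equations(x, y) -> tuple[float, float]:
    """Slope/intercept via the closed-form normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sxx = np.sum(x * x) - np.sum(x) ** 2 / n
    sxy = np.sum(x * y) - np.sum(x) * np.sum(y) / n
    slope = sxy / sxx
    return float(slope), float(y.mean() - slope * x.mean())
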