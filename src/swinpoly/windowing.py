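"""Window geometry for local self-attention.

A feature grid is an ``(h, w, C)`` array of patch tokens (row-major, 0-based,
origin top-left).  Attention is restricted to non-overlapping ``M×M`` windows;
alternate blocks offset the window boundaries by ``(⌊M/2⌋, ⌊M/2⌋)`` to connect
neighbouring windows.  Rather than paying for the extra partial windows that a
shifted partition creates, the grid is cyclically rolled toward the top-left
and re-partitioned regularly, with an additive attention mask confining each
token to the sub-window it originated from — so the window count never grows.

``naive_shifted_partition`` implements the literal shifted partition with
padding and exists as the brute-force oracle the masked path is tested
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MASK_NEG",
    "WindowSet",
    "partition_windows",
    "reverse_windows",
    "cyclic_shift",
    "naive_shifted_partition",
    "build_attention_mask",
    "default_shift",
]

#: Additive bias applied to masked attention logits before softmax.  −1e4 in
#: float32 drives the post-softmax weight of a masked pair below 1e-10.
MASK_NEG = -1.0e4


def default_shift(window_size: int) -> tuple[int, int]:
    """The standard shift for the shifted-window block: (⌊M/2⌋, ⌊M/2⌋)."""
    return (window_size // 2, window_size // 2)


@dataclass
class WindowSet:
    """A batch of M×M token windows plus the bookkeeping to invert the split.

    ``windows`` has shape ``(n_windows, M, M, C)`` in row-major window order.
    ``pad_mask`` (same leading shape, no channel axis) marks real tokens with
    ``True``; it is all-True for regular partitions and marks padding for the
    naive shifted partition.
    """

    windows: np.ndarray
    window_size: int
    origins: list[tuple[int, int]]
    source_shape: tuple[int, int]
    pad_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.pad_mask is None:
            self.pad_mask = np.ones(self.windows.shape[:3], dtype=bool)

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


def partition_windows(grid: np.ndarray, window_size: int) -> WindowSet:
    """Split an (h, w, C) grid into non-overlapping M×M windows.

    Raises ``ValueError`` when h or w is not divisible by M: every resolution
    in the default pipeline is divisible, and silent padding would change the
    window-count accounting.
    """
    grid = np.asarray(grid)
    h, w, c = grid.shape
    m = int(window_size)
    if h % m or w % m:
        raise ValueError(
            f"grid of {h}x{w} patches is not divisible into {m}x{m} windows")
    nh, nw = h // m, w // m
    win = grid.reshape(nh, m, nw, m, c).transpose(0, 2, 1, 3, 4).reshape(-1, m, m, c)
    origins = [(i * m, j * m) for i in range(nh) for j in range(nw)]
    return WindowSet(win, m, origins, (h, w))


def reverse_windows(ws: WindowSet) -> np.ndarray:
    """Invert :func:`partition_windows`; reverse(partition(g)) == g exactly."""
    h, w = ws.source_shape
    m = ws.window_size
    if h % m or w % m or ws.n_windows != (h // m) * (w // m):
        raise ValueError(
            f"window set ({ws.n_windows} windows of {m}) inconsistent with "
            f"source shape {ws.source_shape}")
    c = ws.windows.shape[-1]
    nh, nw = h // m, w // m
    return (ws.windows.reshape(nh, nw, m, m, c)
            .transpose(0, 2, 1, 3, 4).reshape(h, w, c))


def cyclic_shift(grid: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Roll the grid toward the top-left: token (r, c) → ((r−s_r) mod h, (c−s_c) mod w)."""
    return np.roll(np.asarray(grid), (-shift[0], -shift[1]), axis=(0, 1))


def naive_shifted_partition(grid: np.ndarray, window_size: int,
                            shift: tuple[int, int]) -> WindowSet:
    """The literal shifted partition, partial windows padded up to M×M.

    With boundaries offset by `shift`, an h×w grid tiles into up to
    (h/M+1)·(w/M+1) windows (e.g. 2×2 → 3×3 on an 8×8 grid with M=4,
    shift (2,2)).  Used only as the brute-force oracle for the masked
    cyclic-shift strategy.
    """
    grid = np.asarray(grid)
    h, w, c = grid.shape
    m = int(window_size)
    sr, sc = shift[0] % m, shift[1] % m
    # window boundaries start at -(m - s) so that one boundary falls at s
    row_starts = list(range(sr - m if sr else 0, h, m))
    col_starts = list(range(sc - m if sc else 0, w, m))
    windows, origins, masks = [], [], []
    for r0 in row_starts:
        for c0 in col_starts:
            win = np.zeros((m, m, c), dtype=grid.dtype)
            mask = np.zeros((m, m), dtype=bool)
            r1, c1 = max(r0, 0), max(c0, 0)
            r2, c2 = min(r0 + m, h), min(c0 + m, w)
            win[r1 - r0:r2 - r0, c1 - c0:c2 - c0] = grid[r1:r2, c1:c2]
            mask[r1 - r0:r2 - r0, c1 - c0:c2 - c0] = True
            windows.append(win)
            origins.append((r0, c0))
            masks.append(mask)
    return WindowSet(np.stack(windows), m, origins, (h, w),
                     pad_mask=np.stack(masks))


def _region_labels(h: int, w: int, window_size: int,
                   shift: tuple[int, int]) -> np.ndarray:
    """Label each token of the rolled grid by its un-shifted sub-window.

    Tokens sharing a label lay in the same window of the literal shifted
    partition, so attention between different labels must be masked.
    """
    m = int(window_size)
    sr, sc = shift[0] % m, shift[1] % m
    labels = np.zeros((h, w), dtype=np.int64)
    cnt = 0
    row_slices = [slice(0, -m), slice(-m, -sr if sr else None)]
    if sr:
        row_slices.append(slice(-sr, None))
    col_slices = [slice(0, -m), slice(-m, -sc if sc else None)]
    if sc:
        col_slices.append(slice(-sc, None))
    for rs in row_slices:
        for cs in col_slices:
            labels[rs, cs] = cnt
            cnt += 1
    return labels


def build_attention_mask(h: int, w: int, window_size: int,
                         shift: tuple[int, int]) -> np.ndarray:
    """Per-window additive attention bias for the cyclic-shift strategy.

    Returns ``(n_windows, M², M²)`` with 0 where both tokens originate from
    the same sub-window of the un-shifted partition and :data:`MASK_NEG`
    otherwise.  Window count equals the regular partition's (h/M)·(w/M).
    All-zero when shift is (0, 0).
    """
    m = int(window_size)
    if h % m or w % m:
        raise ValueError(
            f"grid of {h}x{w} patches is not divisible into {m}x{m} windows")
    if shift[0] % m == 0 and shift[1] % m == 0:
        n = (h // m) * (w // m)
        return np.zeros((n, m * m, m * m), dtype=np.float32)
    labels = _region_labels(h, w, m, shift)
    ws = partition_windows(labels[..., None].astype(np.float32), m)
    flat = ws.windows.reshape(ws.n_windows, m * m)
    diff = flat[:, :, None] != flat[:, None, :]
    return np.where(diff, np.float32(MASK_NEG), np.float32(0.0))
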