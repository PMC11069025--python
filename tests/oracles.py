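"""Independent brute-force oracles shared across test modules."""

import numpy as np


def flood_fill_labels(binary: np.ndarray, connectivity: int) -> np.ndarray:
    """BFS connected-components labeling, written independently of scipy."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    labels = np.zeros(binary.shape, dtype=int)
    next_label = 0
    for start in np.argwhere(binary):
        start = tuple(start)
        if labels[start]:
            continue
        next_label += 1
        queue = [start]
        labels[start] = next_label
        while queue:
            x, y, z = queue.pop()
            for dx, dy, dz in offsets:
                n = (x + dx, y + dy, z + dz)
                if all(0 <= n[i] < binary.shape[i] for i in range(3)):
                    if binary[n] and not labels[n]:
                        labels[n] = next_label
                        queue.append(n)
    return labels


def same_partition(labels_a: np.ndarray, labels_b: np.ndarray, support: np.ndarray) -> bool:
    """True when two labelings induce the same partition of ``support``."""
    pairs = {(a, b) for a, b in zip(labels_a[support], labels_b[support])}
    return len({a for a, _ in pairs}) == len(pairs) == len({b for _, b in pairs})
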