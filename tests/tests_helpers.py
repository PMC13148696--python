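"""Small shared helpers for the test suite (kept independent of the package
internals they are used to check)."""

import numpy as np


def lattice_centroids(n):
    r, c = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return np.column_stack([c.ravel() + 0.5, -r.ravel() - 0.5]).astype(float)


def flood_fill_connected(cells):
    """Rook-adjacency connectivity by explicit flood fill."""
    cells = set(cells)
    start = next(iter(cells))
    seen = {start}
    stack = [start]
    while stack:
        r, c = stack.pop()
        for nb in ((r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)):
            if nb in cells and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen == cells
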