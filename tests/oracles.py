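"""Independent brute-force oracles shared across test modules."""

import numpy as np


def brute_force_exposure(mesh, active):
    """O(E^2) all-pairs face-matching exposure oracle, independent of the
    packed-face-key implementation."""
    idx = np.flatnonzero(active)
    faces_of = {}
    for e in idx:
        n = mesh.elements[e]
        faces_of[e] = [frozenset(np.delete(n, k)) for k in range(4)]
    out = np.zeros(mesh.n_elements, dtype=int)
    for e in idx:
        exposed = 0
        for f in faces_of[e]:
            shared = sum(1 for other in idx if other != e and f in faces_of[other])
            exposed += shared == 0
        out[e] = exposed
    return out
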