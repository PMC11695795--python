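import numpy as np
import pytest

from circumpen import ct
from circumpen.synthetic import GeneratorConfig, PhantomConfig, gen_ct_phantom


def flood_fill_components(binary: np.ndarray, connectivity: int) -> np.ndarray:
    """Brute-force connected components by BFS flood fill (test oracle)."""
    if connectivity == 6:
        offsets = [
            (dz, dy, dx)
            for dz, dy, dx in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
        ]
    elif connectivity == 26:
        offsets = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    else:
        raise ValueError(connectivity)
    labels = np.zeros(binary.shape, dtype=int)
    current = 0
    for start in zip(*np.nonzero(binary)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                q = (z + dz, y + dy, x + dx)
                if (
                    0 <= q[0] < binary.shape[0]
                    and 0 <= q[1] < binary.shape[1]
                    and 0 <= q[2] < binary.shape[2]
                    and binary[q]
                    and not labels[q]
                ):
                    labels[q] = current
                    stack.append(q)
    return labels


def partition_sets(labels: np.ndarray) -> set[frozenset]:
    """Label-free representation of a component partition."""
    out = {}
    for idx in zip(*np.nonzero(labels)):
        out.setdefault(labels[idx], set()).add(idx)
    return {frozenset(v) for v in out.values()}


@pytest.fixture(scope="session")
def small_phantom():
    """Reduced phantom (3 mm x 4 mm at 24 um) with its analysis volume."""
    cfg = GeneratorConfig(
        seed=11,
        phantom=PhantomConfig(diameter_mm=3.0, height_mm=4.0, halo_decay_mm=0.4),
    )
    grey, binary, truth = gen_ct_phantom(cfg)
    vol = ct.exclude_rim(binary, 0.12)
    return {"config": cfg, "grey": grey, "binary": binary, "vol": vol, "truth": truth}


@pytest.fixture(scope="session")
def default_phantom_run():
    """Default-geometry phantom pushed through the full imprint pipeline."""
    from circumpen.synthetic import phantom_truth_mask

    cfg = GeneratorConfig(seed=7)
    grey, binary, truth = gen_ct_phantom(cfg)
    vol = ct.exclude_rim(binary, 0.24)
    imprint = ct.isolate_imprint(vol)
    profile = ct.radial_porosity_profile(imprint, vol, 2.5)
    return {
        "config": cfg,
        "vol": vol,
        "truth": truth,
        "cone": phantom_truth_mask(cfg),
        "imprint": imprint,
        "profile": profile,
    }
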