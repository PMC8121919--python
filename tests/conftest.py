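import numpy as np
import pandas as pd
import pytest

import snowmorph as sm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def population_2000():
    """The standard synthetic study population: 2000 mixed vignettes."""
    vignettes, labels = sm.generate_population([0.2] * 5, 2000, seed=20160601)
    return vignettes, labels


@pytest.fixture(scope="session")
def features_2000(population_2000):
    vignettes, labels = population_2000
    result = sm.feature_table(vignettes, threshold=245)
    truth = pd.Series(labels, index=result.table.index, name="truth")
    return result.table, truth


@pytest.fixture(scope="session")
def pipeline_2000(features_2000):
    table, truth = features_2000
    config = sm.PipelineConfig(pixel_size_mm=0.088, seed=42)
    return sm.run_pipeline(config, features=table), truth


def random_mask(rng, max_side=15):
    """A random non-empty single-component 8-connected mask."""
    while True:
        shape = (rng.integers(3, max_side + 1), rng.integers(3, max_side + 1))
        m = rng.random(shape) < rng.uniform(0.2, 0.7)
        if not m.any():
            continue
        # keep the largest component via brute-force flood fill
        comps = flood_fill_components(m)
        largest = max(comps, key=len)
        out = np.zeros(shape, dtype=bool)
        for r, c in largest:
            out[r, c] = True
        return out


def flood_fill_components(mask):
    """Exhaustive 8-connected component labelling by flood fill (oracle)."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if mask[r0, c0] and not seen[r0, c0]:
                stack, comp = [(r0, c0)], []
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < mask.shape[0]
                                and 0 <= cc < mask.shape[1]
                                and mask[rr, cc]
                                and not seen[rr, cc]
                            ):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(comp)
    return comps


def brute_force_perimeter(mask):
    """Per-pixel edge count oracle: edges adjacent to background or frame."""
    mask = np.asarray(mask, dtype=bool)
    p = 0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if not mask[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (
                    0 <= rr < mask.shape[0]
                    and 0 <= cc < mask.shape[1]
                    and mask[rr, cc]
                ):
                    p += 1
    return p
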