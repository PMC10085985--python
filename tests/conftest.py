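import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tearfilm import classify as cl
from tearfilm import pipeline
from tearfilm import simulate as sim
from tearfilm.preprocess import preprocess_sequence

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Small render size used throughout the suite; full device resolution only
#: changes pixel counts, not behavior.
TEST_RESOLUTION = (192, 256)


def make_config(breakup_times, seed, **kwargs):
    kwargs.setdefault("resolution", TEST_RESOLUTION)
    return pipeline.config_for_breakup_times(breakup_times, seed=seed, **kwargs)


@pytest.fixture(scope="session")
def noiseless_recording():
    """One fully rendered noiseless recording: (config, sliced seq, gt, records)."""
    config = make_config((2.0, 3.0, 2.5), seed=500, artifact_rate=0.0, noise_sd=0.0)
    seq, gt = sim.generate_sliced(config)
    records = preprocess_sequence(seq, already_sliced=True)
    return config, seq, gt, records


@pytest.fixture(scope="session")
def default_noise_recording():
    """As above but at the default sensor noise (artifacts still off)."""
    config = make_config((2.0, 3.0, 2.5), seed=501, artifact_rate=0.0)
    seq, gt = sim.generate_sliced(config)
    records = preprocess_sequence(seq, already_sliced=True)
    return config, seq, gt, records


@pytest.fixture(scope="session")
def training_set():
    """~600 labeled standardized frames from six default-noise recordings."""
    frames, labels, groups = [], [], []
    for i in range(6):
        config = make_config((2.0 + 0.3 * i, 3.0, 2.5), seed=510 + i, artifact_rate=0.0)
        seq, gt = sim.generate_sliced(config)
        records = preprocess_sequence(seq, already_sliced=True)
        for r in records:
            if r.quality.passed and r.image is not None:
                lab = gt.per_frame_labels[r.source_index]
                if lab in ("positive", "negative"):
                    frames.append(r.image)
                    labels.append(lab)
                    groups.append(i)
    return frames, labels, groups


@pytest.fixture(scope="session")
def trained_model(training_set):
    frames, labels, groups = training_set
    return cl.train_classifier(frames, labels, seed=42, groups=groups)


def brute_force_spots(green, mask, threshold, min_area):
    """Independent spot oracle: threshold + hand-coded flood fill (4+diag).

    Returns a sorted list of component areas of dark pixels inside ``mask``.
    """
    dark = mask & (green < threshold)
    visited = np.zeros_like(dark, dtype=bool)
    h, w = dark.shape
    areas = []
    for sy in range(h):
        for sx in range(w):
            if not dark[sy, sx] or visited[sy, sx]:
                continue
            stack = [(sy, sx)]
            visited[sy, sx] = True
            area = 0
            while stack:
                y, x = stack.pop()
                area += 1
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        if dy == 0 and dx == 0:
                            continue
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and dark[ny, nx] and not visited[ny, nx]:
                            visited[ny, nx] = True
                            stack.append((ny, nx))
            if area >= min_area:
                areas.append(area)
    return sorted(areas)
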