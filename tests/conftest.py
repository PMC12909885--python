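import numpy as np
import pytest

from nutnet.fixtures import FixtureSpec, generate_fixture_dataset, render_fixture_image


def fixture_arrays(n_per_class=16, size=32, seed=3, n_classes=8):
    """Grayscale fixture images as (N,1,H,W) float32 arrays plus labels."""
    xs, ys = [], []
    for ci in range(n_classes):
        for i in range(n_per_class):
            img = render_fixture_image(ci, size, np.random.default_rng([seed, ci, i]))
            xs.append(img.mean(axis=2)[None] / 255.0)
            ys.append(ci)
    return np.asarray(xs, dtype=np.float32), np.asarray(ys, dtype=np.int64)


@pytest.fixture(scope="session")
def small_fixture_arrays():
    return fixture_arrays(n_per_class=16, size=32, seed=3)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A written-to-disk 8x6 fixture dataset at 32x32."""
    root = tmp_path_factory.mktemp("fixtures")
    spec = FixtureSpec(8, 6, 32, seed=5)
    manifest = generate_fixture_dataset(spec, root)
    return root, manifest


def numerical_grad(f, arr, eps=1e-6):
    ng = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = arr[i]
        arr[i] = old + eps
        fp = f()
        arr[i] = old - eps
        fm = f()
        arr[i] = old
        ng[i] = (fp - fm) / (2 * eps)
    return ng
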