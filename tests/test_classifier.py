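"""Atrous-context classifier: context-block hand cases, same-padding,
receptive field, softmax normalization, parameter-count oracles, ablation
arithmetic, gradient flow and training contracts."""

import numpy as np
import pytest

from nutnet import nn
from nutnet.classifier import (ClassifierSpec, TrainConfig, build_classifier,
                               classifier_forward, context_block,
                               count_parameters, export_feature_maps,
                               receptive_field, train_classifier)

rng = np.random.default_rng(0)


def test_context_block_constant_input_identity_kernel():
    """With the 1x1 kernel fixed to identity and zero bias, a constant
    input c per channel gives 2c everywhere (input plus its own mean)."""
    fm = np.zeros((2, 3, 4, 4), dtype=np.float32)
    fm[:, 0], fm[:, 1], fm[:, 2] = 0.5, -1.0, 2.0
    out = context_block(fm)
    np.testing.assert_allclose(out, 2 * fm, atol=1e-6)


def test_context_block_zero_input_zero_output():
    out = context_block(np.zeros((1, 4, 5, 5), dtype=np.float32))
    np.testing.assert_array_equal(out, 0.0)


def test_context_block_pooling_matches_brute_force():
    """The pooled value equals (1/(H*W)) sum over the feature map."""
    fm = rng.standard_normal((3, 5, 6, 7)).astype(np.float32)
    blk = nn.ContextBlock(5, rng=np.random.default_rng(1))
    blk.forward(fm)
    brute = np.array([[fm[b, c].sum() / (6 * 7) for c in range(5)]
                      for b in range(3)])
    np.testing.assert_allclose(blk._pooled, brute, atol=1e-6)


def test_context_block_rejects_empty_spatial():
    blk = nn.ContextBlock(2)
    with pytest.raises(ValueError):
        blk.forward(np.zeros((1, 2, 0, 4), dtype=np.float32))


def test_receptive_field_recurrence():
    """RF = 1 + sum(d_i * (k-1)) = 25 for rates (2, 4, 6), k=3."""
    assert receptive_field(ClassifierSpec()) == 25
    assert receptive_field(ClassifierSpec(dilation_rates=(1,))) == 3
    assert receptive_field(ClassifierSpec(dilation_rates=(2, 4, 6, 8))) == 41


@pytest.mark.parametrize("size", [8, 16, 25, 33, 64])
def test_atrous_stack_preserves_spatial_dims(size):
    from nutnet.classifier import AtrousStack
    stack = AtrousStack(4, 8, (2, 4, 6), "sequential", np.random.default_rng(2))
    x = rng.standard_normal((1, 4, size, size)).astype(np.float32)
    assert stack.forward(x).shape == (1, 8, size, size)


def test_atrous_stack_zero_input_zero_output():
    from nutnet.classifier import AtrousStack
    stack = AtrousStack(3, 6, (2, 4, 6), "sequential", np.random.default_rng(3))
    for conv in stack.convs + [stack.proj]:
        conv.params["b"][...] = 0.0
    out = stack.forward(np.zeros((2, 3, 10, 10), dtype=np.float32))
    np.testing.assert_array_equal(out, 0.0)


def test_softmax_rows_sum_to_one_random_weights():
    spec = ClassifierSpec(in_channels=1, stem_channels=4, atrous_channels=8)
    for seed in range(3):
        model = build_classifier(spec, seed=seed)
        x = np.random.default_rng(seed).standard_normal((4, 1, 16, 16))
        p = classifier_forward(x, model)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert p.shape == (4, 8)


def test_zeroed_final_dense_gives_uniform_eighth():
    spec = ClassifierSpec(in_channels=1, stem_channels=4, atrous_channels=8)
    model = build_classifier(spec, seed=0)
    dense = model.layers[-1]
    dense.params["w"][...] = 0.0
    dense.params["b"][...] = 0.0
    p = classifier_forward(rng.standard_normal((2, 1, 16, 16)), model)
    np.testing.assert_allclose(p, 0.125, atol=1e-7)


def test_parameter_count_single_conv_formula():
    model = nn.Sequential(nn.Conv2d(1, 8, k=3, rng=np.random.default_rng(0)))
    assert model.num_parameters() == (3 * 3 * 1 + 1) * 8 == 80


def test_parameter_count_superlinear_in_width():
    small = count_parameters(ClassifierSpec(atrous_channels=32))
    big = count_parameters(ClassifierSpec(atrous_channels=64))
    assert big > 2 * small


def test_parameter_count_independent_of_image_size():
    spec = ClassifierSpec()
    m1 = build_classifier(spec, seed=0, image_size=32)
    m2 = build_classifier(spec, seed=0, image_size=64)
    assert m1.num_parameters() == m2.num_parameters()


def test_parameter_count_closed_form_full_model():
    """Sum of per-layer formulas for the default architecture."""
    spec = ClassifierSpec(in_channels=1, stem_channels=32, atrous_channels=64)
    stem = (3 * 3 * 1 + 1) * 32 + 2 * 32            # conv + instance norm
    pre = 32 * 32 + 32                              # context block
    atrous = ((3 * 3 * 32 + 1) * 64 + 2 * (3 * 3 * 64 + 1) * 64
              + (1 * 1 * 64 + 1) * 64)              # rates 2,4,6 + 1x1 proj
    post = 64 * 64 + 64
    head = (64 + 1) * 8
    assert count_parameters(spec) == stem + pre + atrous + post + head


def test_context_toggles_change_count_by_block_size():
    """Ablation arithmetic: each context block adds exactly C^2 + C."""
    base = count_parameters(ClassifierSpec(use_pre_context=False,
                                           use_post_context=False))
    pre = count_parameters(ClassifierSpec(use_pre_context=True,
                                          use_post_context=False))
    both = count_parameters(ClassifierSpec(use_pre_context=True,
                                           use_post_context=True))
    assert pre - base == 32 * 32 + 32
    assert both - pre == 64 * 64 + 64


def test_gradient_flow_all_parameters():
    spec = ClassifierSpec(in_channels=1, stem_channels=4, atrous_channels=8,
                          dropout=0.0)
    model = build_classifier(spec, seed=1)
    x = rng.standard_normal((8, 1, 16, 16)).astype(np.float32)
    y = np.arange(8) % 8
    model.train(True)
    logits = model.forward(x)
    _, grad = nn.cross_entropy(logits, y)
    model.zero_grad()
    model.backward(grad)
    for layer, name, arr, _ in model.parameters():
        assert np.linalg.norm(layer.grads[name]) > 0, \
            f"{type(layer).__name__}.{name}"


def test_training_deterministic_with_seed(small_fixture_arrays):
    x, y = small_fixture_arrays
    spec = ClassifierSpec(in_channels=1, stem_channels=4, atrous_channels=8)
    cfg = TrainConfig(epochs=2, batch_size=32, lr=1e-3, seed=9)
    h1 = train_classifier(x, y, spec, cfg).history
    h2 = train_classifier(x, y, spec, cfg).history
    assert h1["train_loss"] == h2["train_loss"]
    assert h1["train_acc"] == h2["train_acc"]


def test_zero_epochs_returns_initialization(small_fixture_arrays):
    x, y = small_fixture_arrays
    spec = ClassifierSpec(in_channels=1, stem_channels=4, atrous_channels=8)
    res = train_classifier(x, y, spec, TrainConfig(epochs=0, seed=3))
    init = build_classifier(spec, seed=3)
    for (_, n1, a1, _), (_, n2, a2, _) in zip(res.model.parameters(),
                                              init.parameters()):
        np.testing.assert_array_equal(a1, a2)


def test_parallel_fusion_mode_runs():
    spec = ClassifierSpec(in_channels=1, stem_channels=4, atrous_channels=8,
                          fusion="parallel")
    model = build_classifier(spec, seed=0)
    p = classifier_forward(rng.standard_normal((2, 1, 16, 16)), model)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


def test_export_feature_maps(tmp_path):
    spec = ClassifierSpec(in_channels=1, stem_channels=4, atrous_channels=8)
    model = build_classifier(spec, seed=0)
    img = rng.standard_normal((1, 32, 32)).astype(np.float32)
    maps = export_feature_maps(model, img,
                               ["stem", "pre_context", "atrous", "post_context"],
                               tmp_path)
    assert set(maps) == {"stem", "pre_context", "atrous", "post_context"}
    for name, m in maps.items():
        assert m.shape == (16, 16)          # after the stride-2 stem
        assert (tmp_path / f"fmap_{name}.png").exists()
    maps2 = export_feature_maps(model, img, ["stem"], tmp_path)
    np.testing.assert_array_equal(maps2["stem"], maps["stem"])
    with pytest.raises(ValueError):
        export_feature_maps(model, img, ["bogus"], tmp_path)


def test_constant_input_constant_stem_map(tmp_path):
    spec = ClassifierSpec(in_channels=1, stem_channels=4, atrous_channels=8)
    model = build_classifier(spec, seed=0)
    img = np.full((1, 32, 32), 0.5, dtype=np.float32)
    maps = export_feature_maps(model, img, ["stem"], tmp_path)
    # constant away from the zero-padded border
    interior = maps["stem"][1:-1, 1:-1]
    assert np.allclose(interior, interior[0, 0])


def test_stacked_four_channel_input(tmp_path, tiny_dataset):
    """The stacked (sobel, canny, ckpf, kernel) variant assembles
    4-channel arrays and feeds a 4-input classifier."""
    from nutnet.classifier import load_dataset_arrays
    from nutnet.data_manager import holdout_test
    from nutnet.filter_bank import FilterConfig, run_filtration
    _, manifest = tiny_dataset
    m = holdout_test(manifest.copy(), 0.5, seed=0)
    m = run_filtration(m, FilterConfig(renderings=("sobel", "canny", "ckpf",
                                                   "kernel")), tmp_path)
    x, y = load_dataset_arrays(m, "test", "stacked")
    assert x.shape == (24, 4, 32, 32)
    spec = ClassifierSpec(in_channels=4, stem_channels=4, atrous_channels=8)
    p = classifier_forward(x[:4], build_classifier(spec, seed=0))
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


def test_spec_validation():
    with pytest.raises(ValueError):
        ClassifierSpec(dilation_rates=(0, 2))
    with pytest.raises(ValueError):
        ClassifierSpec(n_classes=1)
    with pytest.raises(ValueError):
        ClassifierSpec(fusion="concat")
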