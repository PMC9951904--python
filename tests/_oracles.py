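"""Independent closed-form oracles used by the tests.

The parameter oracle re-derives the network's totals from first principles
(spreadsheet-style, one formula per layer), without touching the package's
graph builder, so agreement is a genuine cross-check.
"""

from __future__ import annotations


def conv_params(kh: int, kw: int, cin: int, cout: int) -> int:
    return kh * kw * cin * cout + cout


def expected_network_totals(cfg) -> tuple:
    """(total, trainable, non_trainable, n_layers) from per-layer closed forms."""
    trainable = 0
    bn_channels = 0
    n_layers = 1  # input

    # encoder: two 3x3 convs + pool per stage
    cin = cfg.input_channels
    enc_filters = []
    for level in range(cfg.depth):
        f = cfg.base_filters * cfg.growth**level
        enc_filters.append(f)
        trainable += conv_params(3, 3, cin, f) + conv_params(3, 3, f, f)
        n_layers += 3
        if "encoder" in cfg.bn_scope:
            bn_channels += 2 * f
            n_layers += 2
        cin = f

    # base
    base_f = cfg.base_filters * cfg.growth**cfg.depth
    trainable += conv_params(3, 3, cin, base_f) + conv_params(3, 3, base_f, base_f)
    n_layers += 2
    if "base" in cfg.bn_scope:
        bn_channels += 2 * base_f
        n_layers += 2

    # inception modules, one per skip level
    imp_out = []
    for level in range(cfg.depth):
        spec = cfg.imp_specs[level]
        x = enc_filters[level]
        imp_bn = 0
        for widths in (spec.rep1, spec.rep2):
            trainable += conv_params(1, 1, x, widths.b1)
            trainable += conv_params(1, 1, x, widths.b2_in)
            trainable += conv_params(5, 5, widths.b2_in, widths.b2_out)
            trainable += conv_params(1, 1, x, widths.b3_in)
            trainable += conv_params(3, 3, widths.b3_in, widths.b3_mid)
            trainable += conv_params(3, 3, widths.b3_mid, widths.b3_out)
            trainable += conv_params(1, 1, x, widths.b4)
            imp_bn += sum(widths.all_widths())
            x = widths.concat_channels
            n_layers += 7 + 1 + 1  # convs + pool + concat
        t1, t2 = spec.tail_filters
        trainable += conv_params(3, 3, x, t1) + conv_params(3, 3, t1, t2)
        imp_bn += t1 + t2
        n_layers += 2
        if "imp" in cfg.bn_scope:
            bn_channels += imp_bn
            n_layers += 16
        imp_out.append(t2)

    # decoder, deepest first
    deep = base_f
    for level in range(cfg.depth - 1, -1, -1):
        f = enc_filters[level]
        if cfg.upsample_mode == "transposed_conv":
            trainable += conv_params(2, 2, deep, f)
            n_layers += 1
        else:
            trainable += conv_params(2, 2, deep, f)
            n_layers += 2  # upsample node + conv
        if "upsample" in cfg.bn_scope:
            bn_channels += f
            n_layers += 1
        concat_ch = imp_out[level] + f
        trainable += conv_params(3, 3, concat_ch, f) + conv_params(3, 3, f, f)
        n_layers += 3  # concat + two convs
        if "decoder" in cfg.bn_scope:
            bn_channels += 2 * f
            n_layers += 2
        deep = f

    trainable += conv_params(1, 1, enc_filters[0], cfg.output_channels)
    n_layers += 1

    trainable += 2 * bn_channels
    non_trainable = 2 * bn_channels
    return trainable + non_trainable, trainable, non_trainable, n_layers
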