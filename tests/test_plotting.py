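import io

import numpy as np
import pytest
from PIL import Image

from chromaplot import (
    PlotStyle,
    Selection,
    export_figure,
    fit_baseline_als,
    layer_inventory,
    render,
)

import matplotlib.pyplot as plt


@pytest.fixture(autouse=True)
def close_figures():
    yield
    plt.close("all")


def expected_inventory(chrom, fill, baseline, fractions, vrange, strip):
    """The renderer's decision-tree contract, computed independently."""
    tags = [f"curve:{c.name}" for c in chrom.curves]
    if len(chrom.curves) > 1:
        tags.append("legend")
    if fill:
        tags += [f"fill:{c.name}" for c in chrom.curves]
    if baseline:
        tags += [f"baseline:{c.name}" for c in chrom.curves]
    tags += [f"fraction-highlight:{l}" for l in fractions]
    if vrange:
        tags.append("range-highlight")
    if strip:
        for iv in chrom.intervals():
            tags += [f"fraction-strip-tick:{iv.label}", f"fraction-strip-label:{iv.label}"]
    return sorted(tags)


class TestRenderDecisionTree:
    def test_defaults_draw_only_the_curves(self, small_chrom):
        fig = render(small_chrom)
        inv = layer_inventory(fig)
        assert inv == sorted(
            ["curve:UV 1_280", "curve:UV 2_260", "legend"]
        )
        ax = fig.axes[0]
        assert ax.get_xlabel() == "Elution volume (ml)"
        assert ax.get_ylabel() == "mAU"

    def test_empty_selection_equals_defaults(self, small_chrom):
        inv_default = layer_inventory(render(small_chrom))
        inv_empty = layer_inventory(
            render(small_chrom, PlotStyle(), Selection(selected_fraction_labels=[]))
        )
        assert inv_default == inv_empty

    def test_annotated_render_adds_exactly_its_layers(self, small_chrom):
        baselines = {c.name: fit_baseline_als(c) for c in small_chrom.curves}
        fig = render(
            small_chrom,
            PlotStyle(show_baseline=True, show_fraction_labels_under_plot=True),
            Selection(selected_fraction_labels=["2", "3", "4"]),
            baselines,
        )
        assert layer_inventory(fig) == expected_inventory(
            small_chrom, False, True, ["2", "3", "4"], False, True
        )

    @pytest.mark.parametrize("mask", range(32))
    def test_every_flag_combination_matches_the_contract(self, small_chrom, mask):
        fill = bool(mask & 1)
        baseline = bool(mask & 2)
        fractions = ["2", "5"] if mask & 4 else []
        vrange = (2.2, 3.8) if mask & 8 else None
        strip = bool(mask & 16)
        style = PlotStyle(
            fill_under_curve=fill,
            show_baseline=baseline,
            show_fraction_labels_under_plot=strip,
        )
        sel = Selection(selected_fraction_labels=fractions, volume_range=vrange)
        baselines = (
            {c.name: fit_baseline_als(c) for c in small_chrom.curves}
            if baseline
            else None
        )
        fig = render(small_chrom, style, sel, baselines)
        assert layer_inventory(fig) == expected_inventory(
            small_chrom, fill, baseline, fractions, vrange, strip
        )

    def test_unknown_fraction_label_lists_available(self, small_chrom):
        with pytest.raises(KeyError, match="available"):
            render(small_chrom, selection=Selection(selected_fraction_labels=["T99"]))

    def test_rendering_is_deterministic(self, small_chrom):
        style = PlotStyle(fill_under_curve=True, show_fraction_labels_under_plot=True)
        sel = Selection(selected_fraction_labels=["3"], volume_range=(2.0, 4.0))

        def png_bytes():
            fig = render(small_chrom, style, sel)
            buf = io.BytesIO()
            fig.savefig(buf, format="png", dpi=100)
            return layer_inventory(fig), buf.getvalue()

        inv1, png1 = png_bytes()
        inv2, png2 = png_bytes()
        assert inv1 == inv2
        assert png1 == png2


class TestExport:
    def test_tiff_pixel_dimensions(self, small_chrom, tmp_path):
        path = tmp_path / "fig.tiff"
        export_figure(render(small_chrom), path, dpi=300, size_inches=(6, 4))
        with Image.open(path) as img:
            assert img.size == (1800, 1200)

    @pytest.mark.parametrize(
        "fmt,magic",
        [
            ("pdf", b"%PDF"),
            ("eps", b"%!PS"),
            ("png", b"\x89PNG"),
            ("tiff", (b"II*\x00", b"MM\x00*")),
        ],
    )
    def test_format_signatures(self, small_chrom, tmp_path, fmt, magic):
        path = tmp_path / f"fig.{fmt}"
        export_figure(render(small_chrom), path)
        head = path.read_bytes()[:4]
        if isinstance(magic, tuple):
            assert head in magic
        else:
            assert head.startswith(magic)
        assert path.stat().st_size > 0

    def test_unsupported_format_names_the_supported_ones(self, small_chrom, tmp_path):
        with pytest.raises(ValueError, match="pdf, eps, tiff, png"):
            export_figure(render(small_chrom), tmp_path / "fig.svg")

    def test_failed_export_leaves_no_partial_file(self, small_chrom, tmp_path, monkeypatch):
        fig = render(small_chrom)
        missing_dir = tmp_path / "not" / "here" / "fig.png"
        with pytest.raises(OSError):
            export_figure(fig, missing_dir)
        assert not missing_dir.exists()

        # simulated failure mid-write: temp file must be cleaned up
        target = tmp_path / "fig.png"

        def boom(*a, **k):
            raise RuntimeError("disk on fire")

        monkeypatch.setattr(fig, "savefig", boom)
        with pytest.raises(RuntimeError):
            export_figure(fig, target)
        assert not target.exists()
        assert list(tmp_path.iterdir()) == []

    def test_repeated_pdf_exports_identical_bytes(self, small_chrom, tmp_path):
        p1, p2 = tmp_path / "a.pdf", tmp_path / "b.pdf"
        export_figure(render(small_chrom), p1)
        export_figure(render(small_chrom), p2)
        assert p1.read_bytes() == p2.read_bytes()
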