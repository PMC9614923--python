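import pytest
from PIL import Image

from antmark import mot_io, synthetic


@pytest.fixture()
def tiny_config():
    """Small, fast indoor simulation configuration."""
    return synthetic.SimConfig(
        n_ants=3,
        n_frames=20,
        image_size=(320, 240),
        body_length_px=20.0,
        body_length_m=0.0106,
        box_size=16,
        seed=11,
    )


@pytest.fixture()
def tiny_outdoor_config():
    return synthetic.SimConfig.outdoor(
        n_ants=8,
        n_frames=40,
        image_size=(320, 240),
        nest_point=(160.0, 120.0),
        body_length_px=20.0,
        box_size=16,
        seed=13,
    )


@pytest.fixture()
def image_set_dir(tmp_path):
    """An image-set folder with blank frames, named by the folder grammar."""

    def _make(seq_label="0001", n_objects=2, box_size=16, n_frames=12, size=(64, 48)):
        name = str(mot_io.ImageSetName(seq_label, n_objects, box_size))
        d = tmp_path / name
        img = d / "img"
        if img.exists():
            return d
        img.mkdir(parents=True)
        for i in range(1, n_frames + 1):
            Image.new("RGB", size, (220, 220, 220)).save(img / mot_io.frame_filename(i))
        return d

    return _make
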