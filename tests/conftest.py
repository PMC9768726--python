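import pytest

from dropphase import (
    DropletSpec,
    OpticsSpec,
    PunctaSpec,
    SceneSpec,
    render_scene,
)

IDENTITY_2CH = ((1.0, 0.0), (0.0, 1.0))


@pytest.fixture
def noiseless_optics():
    """Two-fluorophore optics with no noise, for exact forward-model checks."""
    return OpticsSpec(
        gains={"EGFP": 2.0, "Alexa647": 2.0},
        background=10.0,
        noise_sd=0.0,
        pixel_size=1.0,
        puncta=PunctaSpec(count_range=(1, 3), radius_range=(2.0, 4.0), contrast=2.0),
    )


def make_scene(
    droplets,
    optics,
    shape=(256, 256),
    crosstalk=IDENTITY_2CH,
    seed=0,
    allow_edge=False,
):
    """Two-channel scene with a protein and a crowder component."""
    return SceneSpec(
        image_shape=shape,
        droplets=tuple(droplets),
        optics=optics,
        channels=("ch_green", "ch_farred"),
        fluorophores=("EGFP", "Alexa647"),
        crosstalk=crosstalk,
        fluorophore_of={"protein": "EGFP", "crowder": "Alexa647"},
        condensate_component="protein",
        seed=seed,
        allow_edge=allow_edge,
    )


def disc_scene(
    conc=50.0, radius=30.0, centre=(128.0, 128.0), label="homogeneous", **kwargs
):
    """Single-droplet scene carrying only the protein component."""
    optics = kwargs.pop("optics", None) or OpticsSpec(
        gains={"EGFP": 2.0, "Alexa647": 2.0}, background=10.0, noise_sd=0.0
    )
    droplet = DropletSpec(centre[0], centre[1], radius, {"protein": conc}, label)
    return make_scene([droplet], optics, **kwargs)


@pytest.fixture
def rendered_disc():
    """(ImageSet, manifest) for one noiseless homogeneous droplet."""
    return render_scene(disc_scene())
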