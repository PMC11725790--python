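import numpy as np
import pytest

from cryomesh import RunConfig, generate_scene
from cryomesh.synthetic import GENOTYPE_PRESETS, AssemblyPreset, Genotype, ScenePreset, Sphere


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def wt_scene():
    """One default wild-type scene, shared across tests that only read it."""
    return generate_scene("WT", 7)


def small_preset(genotype="WT") -> ScenePreset:
    """A shrunken scene preset so pipeline-level tests stay fast."""
    preset = GENOTYPE_PRESETS[Genotype(genotype)]()
    d = dict(preset.assembly.__dict__)
    d.update(n_filaments=15, filament_length=400.0)
    d["confinement"] = Sphere((0, 0, 0), 60.0)
    preset.assembly = AssemblyPreset(**d)
    preset.cell_radius = 200.0
    preset.cell_half_length = 260.0
    preset.nucleoid_dims = (400.0, 120.0, 120.0)
    preset.nucleoid_center_y = -100.0
    preset.nucleoid_n_filaments = 12
    preset.ribosome_intensity = 1.0e-5
    return preset


def _small_override():
    return {
        "cell_radius": 200.0,
        "cell_half_length": 260.0,
        "nucleoid_dims": [400.0, 120.0, 120.0],
        "nucleoid_center_y": -100.0,
        "nucleoid_n_filaments": 12,
        "ribosome_intensity": 1.0e-5,
        "assembly": {"n_filaments": 15, "filament_length": 400.0,
                     "sphere_radius": 60.0},
    }


SMALL_OVERRIDES = {"WT": _small_override(), "dPomY": _small_override()}


@pytest.fixture
def small_config():
    return RunConfig(genotype_overrides=SMALL_OVERRIDES)
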