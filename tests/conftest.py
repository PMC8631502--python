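import pytest

from fishglycomics import NoiseModel, PipelineConfig, build_presets, generate_ms1
from fishglycomics.glycan_model import parse_topology


@pytest.fixture(scope="session")
def presets():
    return build_presets()


@pytest.fixture()
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def salmon_clean(presets):
    """Noise-free Atlantic-salmon MS1 peak list with its ground truth."""
    return generate_ms1(presets["atlantic-salmon"], seed=1,
                        noise=NoiseModel.silent())


@pytest.fixture(scope="session")
def topologies():
    """Named topologies exercised throughout: antenna epitopes and full glycans."""
    return {
        "sturgeon_epitope": parse_topology("Gal(a1-?)[Gal(b1-?)]Gal(b1-?)GlcNAc"),
        "catfish_epitope": parse_topology("NeuAc(a2-?)[Gal(b1-?)]Gal(b1-?)GlcNAc"),
        "galgal_epitope": parse_topology("Gal(b1-?)Gal(b1-?)GlcNAc"),
        "disa_antenna": parse_topology(
            "NeuAc(a2-8)NeuAc(a2-3)Gal(b1-4)GlcNAc"),
        "branched_hex3": parse_topology("Gal(b1-?)[Gal(b1-?)]Gal(b1-?)GlcNAc"),
        "linear_hex3": parse_topology("Gal(b1-?)Gal(b1-?)Gal(b1-?)GlcNAc"),
        "biantennary_disial": parse_topology(
            "NeuAc(a2-3)Gal(b1-4)GlcNAc(b1-2)Man(a1-3)"
            "[NeuAc(a2-3)Gal(b1-4)GlcNAc(b1-2)Man(a1-6)]"
            "Man(b1-4)GlcNAc(b1-4)GlcNAc"),
        "sturgeon_biantennary": parse_topology(
            "Gal(a1-?)[Gal(b1-?)]Gal(b1-?)GlcNAc(b1-2)Man(a1-3)"
            "[Gal(a1-?)[Gal(b1-?)]Gal(b1-?)GlcNAc(b1-2)Man(a1-6)]"
            "Man(b1-4)GlcNAc(b1-4)GlcNAc"),
        "catfish_mixed": parse_topology(
            "NeuAc(a2-?)[Gal(b1-?)]Gal(b1-?)GlcNAc(b1-2)Man(a1-3)"
            "[Gal(b1-?)Gal(b1-?)GlcNAc(b1-2)Man(a1-6)]"
            "Man(b1-4)GlcNAc(b1-4)GlcNAc"),
    }
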