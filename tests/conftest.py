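import pytest
from hypothesis import settings

from ovastereo import OvaryConfig, SizeDist, StageConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


# A small ovary (10 mm long axis -> 10 slabs of 1 mm, 200 sections each)
# keeps whole-pipeline tests fast while preserving the default design's
# clean arithmetic (no partial slabs or section groups).
SMALL_AXES = (2500.0, 3000.0, 5000.0)


def small_config(**kw) -> OvaryConfig:
    kw.setdefault("semi_axes", SMALL_AXES)
    kw.setdefault("cortex_thickness", 800.0)
    return OvaryConfig(**kw)


def mixed_stages(n_primordial=120, n_primary=40, n_secondary=15, n_antral=3):
    base = OvaryConfig().stages
    return {
        "primordial": StageConfig(n_primordial, base["primordial"].follicle,
                                  base["primordial"].oocyte, base["primordial"].nucleus,
                                  base["primordial"].nucleolus),
        "primary": StageConfig(n_primary, base["primary"].follicle,
                               base["primary"].oocyte, base["primary"].nucleus,
                               base["primary"].nucleolus),
        "secondary": StageConfig(n_secondary, base["secondary"].follicle,
                                 base["secondary"].oocyte, base["secondary"].nucleus,
                                 base["secondary"].nucleolus),
        "antral": StageConfig(n_antral, SizeDist(600, 50), SizeDist(100, 8),
                              SizeDist(30, 2.5), SizeDist(5, 0.5)),
    }


@pytest.fixture(scope="session")
def small_mixed_model():
    from ovastereo import generate_ovary
    return generate_ovary(small_config(stages=mixed_stages()), seed=11)
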