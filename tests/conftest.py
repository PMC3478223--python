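import numpy as np
import pytest

from karyotex.datatypes import NucleusImage


def make_disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius - 2 : radius + 3, -radius - 2 : radius + 3]
    return xx**2 + yy**2 <= radius**2


def make_nucleus(gray, mask=None, **kwargs) -> NucleusImage:
    gray = np.asarray(gray)
    if mask is None:
        mask = np.ones(gray.shape, dtype=bool)
    return NucleusImage(gray=gray, mask=np.asarray(mask, dtype=bool), **kwargs)


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A tiny written-out cohort shared by the pipeline tests."""
    from karyotex.synthetic import GeneratorConfig, generate_cohort, write_cohort

    config = GeneratorConfig(
        seed=11, n_patients_per_group=2, nuclei_per_patient=4
    )
    for gp in config.group_params.values():
        gp.area_um2_range = (30.0, 50.0)
    outdir = tmp_path_factory.mktemp("cohort")
    bundle = generate_cohort(config)
    paths = write_cohort(bundle, outdir)
    return {"dir": outdir, "bundle": bundle, "config": config, **paths}
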