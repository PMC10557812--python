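"""Shared fixtures: small phantoms and the (expensive, session-scoped)
two-stage domain-generalization study."""

from __future__ import annotations

import pytest

from ddgen import CohortSpec, Dim3, DomainSpec, generate_cohort, make_atlas
from ddgen.study import StudyRun, run_study_seed


@pytest.fixture(scope="session")
def small_dims() -> Dim3:
    return Dim3(16, 16, 16)


@pytest.fixture(scope="session")
def small_atlas(small_dims):
    return make_atlas(small_dims, 6, seed=0)


def make_cohort_spec(dims, atlas, *, n_per=4, seed=1, effect_size=0.5,
                     domains=None, grade_noise=0.0) -> CohortSpec:
    """Cohort spec whose disease regions are the two largest atlas regions
    (class 1 the second largest, class 2 the largest)."""
    big = sorted(atlas.region_volumes, key=atlas.region_volumes.get,
                 reverse=True)
    if domains is None:
        domains = [DomainSpec("src", 1.0, 0.0, 4.0, 0.02)]
    return CohortSpec(
        dims=dims,
        n_classes=3,
        disease_regions={1: {big[1]}, 2: {big[0]}},
        effect_size=effect_size,
        domains=domains,
        n_per_class_per_domain=n_per,
        seed=seed,
        grade_noise=grade_noise,
    )


@pytest.fixture(scope="session")
def small_cohort(small_dims, small_atlas):
    spec = make_cohort_spec(small_dims, small_atlas)
    samples, grades = generate_cohort(spec, small_atlas)
    return spec, samples, grades


@pytest.fixture(scope="session")
def dg_study() -> list[StudyRun]:
    """Full two-stage domain-shift study over three seeds (several
    minutes; shared by the end-to-end tests)."""
    return [run_study_seed(s) for s in (1, 2, 3)]
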