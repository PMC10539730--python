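import numpy as np
import pytest
from hypothesis import settings

import xecest as x

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def field_1t() -> x.FieldConfig:
    """Benchtop magnet: 129Xe Larmor frequency 12.09 MHz."""
    return x.FieldConfig(larmor_mhz=12.09)


@pytest.fixture
def field_117t() -> x.FieldConfig:
    """11.7 T spectrometer: 129Xe Larmor frequency 138.36 MHz."""
    return x.FieldConfig(larmor_mhz=138.36)


@pytest.fixture
def benchtop_system(field_1t) -> x.ExchangeSystem:
    """Single cryptophane at 1 T with realistic weak-saturation relaxation."""
    return x.ExchangeSystem(
        field=field_1t,
        free=x.FreePool(delta_ppm=196, r1=0.01, r2=20),
        bound=(x.BoundPool(f=0.04, k_out=50, delta_ppm=52),),
    )


@pytest.fixture
def highfield_system(field_117t) -> x.ExchangeSystem:
    """Single cryptophane at 11.7 T (strong-saturation reference point)."""
    return x.ExchangeSystem(
        field=field_117t,
        free=x.FreePool(delta_ppm=196, r1=0.01, r2=50),
        bound=(x.BoundPool(f=0.04, k_out=50, delta_ppm=52),),
    )


@pytest.fixture
def mixture_system(field_1t) -> x.ExchangeSystem:
    """Two-cryptophane mixture at 1 T (bound xenon at 52 and 42 ppm)."""
    return x.ExchangeSystem(
        field=field_1t,
        free=x.FreePool(delta_ppm=196, r1=0.1, r2=10),
        bound=(
            x.BoundPool(f=0.037, k_out=50, delta_ppm=52),
            x.BoundPool(f=0.025, k_out=100, delta_ppm=42),
        ),
    )


@pytest.fixture
def tube() -> x.TubeGeometry:
    return x.TubeGeometry(inner_diameter_m=0.0043)


@pytest.fixture
def benchtop_gradients() -> x.GradientScheme:
    return x.GradientScheme(g_sat=0.021, g_acq=0.084)


def make_mixture_ufz(
    system, *, omega1=64.7, rf_offset=47.0, t_sat=3.0,
    g_sat=0.021, g_acq=0.084, n_positions=512, noise_sigma=0.0, seed=0,
    off_scale=1.0,
) -> x.UfzExperiment:
    return x.UfzExperiment(
        system=system,
        sat=x.SaturationScheme(omega1=omega1, offset_ppm=rf_offset, t_sat=t_sat),
        geometry=x.TubeGeometry(inner_diameter_m=0.0043),
        gradients=x.GradientScheme(g_sat=g_sat, g_acq=g_acq),
        n_positions=n_positions,
        noise_sigma=noise_sigma,
        off_scale=off_scale,
        rng_seed=seed,
    )
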