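"""Global DAS fitting, DAS -> SAS transforms and target kinetic fits."""

import numpy as np
import pytest

from pbsdyn.errors import ModelInconsistencyError
from pbsdyn.kinetics import (
    IRFModel,
    annotate_components,
    parallel_scheme,
    sequential_scheme,
)
from pbsdyn.geometry import RankingEntry, RankingReport
from pbsdyn.models import (
    GlobalDecayModel,
    SchemeTemplate,
    TargetKineticModel,
    Transition,
    das_to_sas,
    rod_scheme_template,
)
from pbsdyn.simulate import Band, SurfaceSpec, make_surface, species_spectra


# ---------------------------------------------------------------------------
# GlobalDecayModel
# ---------------------------------------------------------------------------


def test_noiseless_two_exponential_recovery(noiseless_two_exp_surface):
    surface, spec = noiseless_two_exp_surface
    res = GlobalDecayModel(surface, 2, irf=spec.irf,
                          init_lifetimes=[2.0, 500.0]).fit()
    assert res.converged
    np.testing.assert_allclose(res.lifetimes, [5.0, 200.0], rtol=1e-3)
    assert res.fit_residual_rms < 1e-8


def test_single_component_self_consistency():
    """n=1 on a 1-component surface returns the band shape up to scale."""
    times = np.linspace(-1.0, 500.0, 200)
    wavelengths = np.linspace(550.0, 720.0, 60)
    irf = IRFModel(0.0, 0.2)
    spec = SurfaceSpec(
        scheme=parallel_scheme([80.0], populations=[1.0]),
        bands=((Band(650.0, 12.0, -1.0),),),
        irf=irf,
        noise_sigma=0.0,
    )
    surface = make_surface(spec, times, wavelengths)
    res = GlobalDecayModel(surface, 1, irf=irf).fit()
    assert res.lifetimes[0] == pytest.approx(80.0, rel=1e-4)
    band = species_spectra(spec, wavelengths)[0]
    amp = res.amplitude_spectra[0]
    scale = amp[np.argmax(np.abs(amp))] / band[np.argmax(np.abs(band))]
    np.testing.assert_allclose(amp, band * scale, atol=1e-6 * np.abs(band).max())


def test_residual_monotone_in_components(noisy_rod_surface):
    surface, spec = noisy_rod_surface
    rms = []
    for n in (1, 2, 3, 4):
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rms.append(GlobalDecayModel(surface, n, irf=spec.irf).fit().fit_residual_rms)
    assert all(b <= a + 1e-12 for a, b in zip(rms, rms[1:]))


def test_das_deterministic(noisy_rod_surface):
    surface, spec = noisy_rod_surface
    r1 = GlobalDecayModel(surface, 3, irf=spec.irf).fit()
    r2 = GlobalDecayModel(surface, 3, irf=spec.irf).fit()
    np.testing.assert_array_equal(r1.lifetimes, r2.lifetimes)
    np.testing.assert_array_equal(r1.amplitude_spectra, r2.amplitude_spectra)


def test_lifetime_beyond_window_flagged():
    """A decay much slower than the scan window is reported as a bound."""
    times = np.linspace(0.0, 100.0, 80)
    wavelengths = np.linspace(600.0, 700.0, 30)
    spec = SurfaceSpec(
        scheme=parallel_scheme([2000.0], populations=[1.0]),
        bands=((Band(650.0, 10.0, 1.0),),),
        irf=None,
        noise_sigma=0.0,
    )
    res = GlobalDecayModel(make_surface(spec, times, wavelengths), 1, irf=None).fit()
    assert bool(res.poorly_determined[0])
    assert "lower bound" in res.summary()


def test_overfitting_warns(noiseless_two_exp_surface):
    surface, spec = noiseless_two_exp_surface
    with pytest.warns(UserWarning, match="SVD rank"):
        GlobalDecayModel(surface, 6, irf=spec.irf)


# ---------------------------------------------------------------------------
# das_to_sas
# ---------------------------------------------------------------------------


def test_single_compartment_sas_equals_das():
    times = np.linspace(-1.0, 400.0, 150)
    wavelengths = np.linspace(600.0, 700.0, 40)
    irf = IRFModel(0.0, 0.2)
    scheme = parallel_scheme([60.0], populations=[1.0])
    spec = SurfaceSpec(scheme=scheme, bands=((Band(650.0, 10.0, -1.0),),),
                       irf=irf, noise_sigma=0.0)
    das = GlobalDecayModel(make_surface(spec, times, wavelengths), 1, irf=irf).fit()
    sas = das_to_sas(das, scheme)
    np.testing.assert_allclose(sas.species_spectra, das.amplitude_spectra, atol=1e-10)


def test_parallel_scheme_sas_componentwise_das():
    """With a diagonal K and per-compartment initial populations, each SAS is
    the DAS divided by its initial weight."""
    times = np.linspace(-1.0, 1500.0, 250)
    wavelengths = np.linspace(560.0, 720.0, 50)
    irf = IRFModel(0.0, 0.2)
    scheme = parallel_scheme([5.0, 200.0], populations=[0.5, 0.5])
    spec = SurfaceSpec(
        scheme=scheme,
        bands=((Band(620.0, 10.0, -1.0),), (Band(670.0, 10.0, -1.0),)),
        irf=irf, noise_sigma=0.0,
    )
    surface = make_surface(spec, times, wavelengths)
    das = GlobalDecayModel(surface, 2, irf=irf, init_lifetimes=[3.0, 300.0]).fit()
    sas = das_to_sas(das, scheme)
    truth = species_spectra(spec, wavelengths)
    np.testing.assert_allclose(sas.species_spectra, truth, atol=1e-6)
    # componentwise proportionality to the DAS (scale = initial population)
    np.testing.assert_allclose(das.amplitude_spectra, 0.5 * sas.species_spectra,
                               atol=1e-6)


def test_sequential_sas_round_trip():
    """simulate -> global fit -> impose scheme recovers the generating bands."""
    times = np.linspace(-2.0, 3000.0, 300)
    wavelengths = np.linspace(560.0, 720.0, 60)
    irf = IRFModel(0.0, 0.3)
    scheme = sequential_scheme([10.0, 120.0, 900.0])
    spec = SurfaceSpec(
        scheme=scheme,
        bands=(
            (Band(620.0, 10.0, -1.0),),
            (Band(650.0, 10.0, -0.8),),
            (Band(680.0, 10.0, -0.6),),
        ),
        irf=irf,
        noise_sigma=0.0,
    )
    surface = make_surface(spec, times, wavelengths)
    das = GlobalDecayModel(surface, 3, irf=irf,
                           init_lifetimes=[5.0, 80.0, 1500.0]).fit()
    sas = das_to_sas(das, scheme)
    truth = species_spectra(spec, wavelengths)
    assert np.max(np.abs(sas.species_spectra - truth)) < 0.01 * np.abs(truth).max()


def test_das_sas_reconstruction_identity(noiseless_two_exp_surface):
    surface, spec = noiseless_two_exp_surface
    das = GlobalDecayModel(surface, 2, irf=spec.irf,
                           init_lifetimes=[2.0, 500.0]).fit()
    sas = das_to_sas(das, spec.scheme)
    assert np.max(np.abs(sas.reconstruction() - das.reconstruction())) < 1e-10


def test_das_to_sas_lifetime_mismatch_raises(noiseless_two_exp_surface):
    surface, spec = noiseless_two_exp_surface
    das = GlobalDecayModel(surface, 2, irf=spec.irf,
                           init_lifetimes=[2.0, 500.0]).fit()
    wrong = sequential_scheme([50.0, 400.0])
    with pytest.raises(ModelInconsistencyError):
        das_to_sas(das, wrong)


# ---------------------------------------------------------------------------
# TargetKineticModel
# ---------------------------------------------------------------------------


def _two_step_template(tau1, tau2):
    return SchemeTemplate(
        compartment_names=("S1", "S2"),
        transitions=(Transition("S1", "S2", "k1"), Transition("S2", None, "k2")),
        initial_populations=np.array([1.0, 0.0]),
        init_rates={"k1": 1.0 / tau1, "k2": 1.0 / tau2},
    )


def test_target_fit_noiseless_two_step(noiseless_two_exp_surface):
    surface, spec = noiseless_two_exp_surface
    res = TargetKineticModel(surface, _two_step_template(3.0, 400.0),
                             irf=spec.irf).fit()
    assert res.converged
    assert res.lifetimes["k1"] == pytest.approx(5.0, rel=1e-3)
    assert res.lifetimes["k2"] == pytest.approx(200.0, rel=1e-3)
    assert res.fit_residual_rms < 1e-8


def test_target_single_compartment_rate_is_inverse_lifetime():
    times = np.linspace(0.0, 400.0, 150)
    wavelengths = np.linspace(600.0, 700.0, 30)
    spec = SurfaceSpec(
        scheme=parallel_scheme([75.0], populations=[1.0]),
        bands=((Band(650.0, 10.0, 1.0),),),
        irf=None, noise_sigma=0.0,
    )
    surface = make_surface(spec, times, wavelengths)
    template = SchemeTemplate(
        ("S1",), (Transition("S1", None, "k"),), np.array([1.0]), {"k": 1.0 / 30.0}
    )
    res = TargetKineticModel(surface, template).fit()
    assert res.rates["k"] == pytest.approx(1.0 / 75.0, rel=1e-6)


def test_target_rod_scheme_recovers_slowest(noisy_rod_surface):
    """Branched rod-topology target fit recovers the terminal lifetime at 1% noise."""
    surface, spec = noisy_rod_surface
    template = rod_scheme_template(tau_p1=5.0, tau_p2=35.0, tau_r=120.0,
                                   tau_t=1200.0)
    res = TargetKineticModel(surface, template, irf=spec.irf).fit()
    assert res.converged
    assert res.lifetimes["k_t"] == pytest.approx(1999.0, rel=0.15)
    # degeneracy diagnostics are exposed for every rate
    assert set(res.rate_stderr) == {"k_p1", "k_p2", "k_r", "k_t"}
    assert "tau (ps)" in res.summary()


def test_target_equivalent_to_das_to_sas_on_noiseless_data(noiseless_two_exp_surface):
    surface, spec = noiseless_two_exp_surface
    das = GlobalDecayModel(surface, 2, irf=spec.irf,
                           init_lifetimes=[2.0, 500.0]).fit()
    sas = das_to_sas(das, spec.scheme)
    tgt = TargetKineticModel(surface, _two_step_template(3.0, 300.0),
                             irf=spec.irf).fit()
    np.testing.assert_allclose(tgt.sas.species_spectra, sas.species_spectra,
                               atol=1e-5)


# ---------------------------------------------------------------------------
# component annotation
# ---------------------------------------------------------------------------


def _ranking():
    return RankingReport(
        entries=(
            RankingEntry("1I-b82-2", -41.0, 5),
            RankingEntry("1I-b82-1", -54.0, 7),
            RankingEntry("1I-b82-3", -58.0, 4),
        )
    )


def test_annotation_four_components():
    """The slowest component lands on the flattest bottom-trimer bilin."""
    out = annotate_components([3.6, 25.0, 200.0, 1999.0], _ranking(),
                              component_labels=["P1", "P2", "R", "T"])
    by_label = {a.component_label: a.assigned_bilins for a in out}
    assert by_label["P1"] == ("a84", "b155")
    assert by_label["T"] == ("1I-b82-2",)
    # intermediates: least flat candidate first
    assert by_label["P2"] == ("1I-b82-3",)
    assert by_label["R"] == ("1I-b82-1",)


def test_annotation_single_component_single_bilin():
    ranking = RankingReport(entries=(RankingEntry("only", -10.0, 1),))
    out = annotate_components([100.0], ranking)
    assert out[0].assigned_bilins == ("only",)


def test_annotation_partial_with_warning():
    """Five components against three structural classes leaves two unmapped."""
    ranking = RankingReport(
        entries=(RankingEntry("flat", -41.0, 5), RankingEntry("mid", -54.0, 3))
    )
    with pytest.warns(UserWarning, match="no structural class"):
        out = annotate_components([1.0, 5.0, 20.0, 100.0, 500.0], ranking)
    unassigned = [a for a in out if not a.assigned_bilins]
    assert len(unassigned) == 2
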