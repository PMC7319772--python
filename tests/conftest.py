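"""Shared fixtures: one fully analysed synthetic session reused across tests."""

from dataclasses import dataclass

import numpy as np
import pytest

import spindlenest as sn

FS = 600.0


@dataclass
class AnalysedSession:
    session: sn.Session
    truth: sn.GroundTruth
    delta: sn.BandSignal
    spindle: sn.BandSignal
    ripple: sn.BandSignal
    rest: sn.StateIntervals
    kcs: sn.EventSeries
    troughs: sn.EventSeries
    swrs: sn.EventSeries
    cycles: list


@pytest.fixture(scope="session")
def analysed() -> AnalysedSession:
    """A default synthetic session run through the whole detection pipeline."""
    session, truth = sn.simulate_session(sn.SimConfig(seed=11))
    delta = sn.filter_band(session.lfp["mpfc"], FS, "delta", "mpfc")
    spindle = sn.filter_band(session.lfp["mpfc"], FS, "spindle", "mpfc")
    ripple = sn.filter_band(session.lfp["ca1"], FS, "ripple", "ca1")
    rest = sn.detect_rest_intervals(sn.power_envelope(delta, 10.0),
                                    sn.power_envelope(ripple, 10.0), FS)
    kcs = sn.detect_kcomplexes(delta, rest)
    troughs = sn.detect_spindle_troughs(spindle, rest)
    swrs = sn.detect_swrs(ripple, rest)
    cycles = sn.segment_spindle_cycles(spindle, troughs)
    cycles = sn.cycle_ripple_power(cycles, ripple)
    return AnalysedSession(session, truth, delta, spindle, ripple, rest,
                           kcs, troughs, swrs, cycles)


@pytest.fixture()
def rest_all():
    """A trivial StateIntervals covering [0, 1000) s entirely as rest."""
    return sn.StateIntervals(rest=np.array([[0.0, 1000.0]]),
                             wake=np.empty((0, 2)), extent=(0.0, 1000.0))


def make_rest(extent, rest_intervals):
    rest = np.asarray(rest_intervals, dtype=float).reshape(-1, 2)
    return sn.StateIntervals(rest=rest,
                             wake=sn.complement_intervals(rest, extent),
                             extent=extent)
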