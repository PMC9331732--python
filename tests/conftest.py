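import pytest

from kvclamp import analysis, library, protocols, simulate


def protocol_battery(tail_V: float) -> dict:
    return {
        "iv": protocols.build_iv_protocol(),
        "tail": protocols.build_tail_protocol(tail_V),
        "deactivation": protocols.build_deactivation_protocol(),
        "inactivation": protocols.build_inactivation_protocol(),
        "recovery": protocols.build_recovery_protocol(),
    }


@pytest.fixture(scope="session")
def ref_species():
    return library.reference_species()


@pytest.fixture(scope="session")
def characterized_trio(ref_species):
    """Noise-free full-battery simulation + characterization of the three
    reference channel populations (shared across tests; expensive)."""
    tails = library.reference_tail_potentials()
    out = {}
    for name, sp in ref_species.items():
        prots = protocol_battery(tails[name])
        rec = simulate.simulate_cell(sp, list(prots.values()))
        out[name] = analysis.characterize_cell(rec, prots)
    return out
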