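import numpy as np
import pytest

from hdxstab import (
    ProteinEntry,
    SyntheticSystem,
    compute_intrinsic_rates,
)


@pytest.fixture
def toy_sequence():
    # proline at position 14, no proline in the first peptide windows
    return "MKTAYIAKQRQISPVKSHFSRQLEERLGLIEVQA"


@pytest.fixture
def toy_system(toy_sequence):
    rng = np.random.default_rng(42)
    rates = compute_intrinsic_rates(toy_sequence, override=0.05)
    return SyntheticSystem(
        protein=ProteinEntry(name="toy", sequence=toy_sequence),
        log_protection=rng.uniform(0.0, 5.0, len(toy_sequence)),
        intrinsic_rates=rates,
        back_exchange_retention=0.7,
        noise_sd=0.2,
        seed=7,
    )


def make_record(**overrides):
    from hdxstab import PeptideUptakeRecord

    defaults = dict(
        protein="toy",
        start=2,
        end=11,
        sequence="KTAYIAKQRQ",
        condition="vehicle",
        exposure=60.0,
        m0=1000.0,
        mt=1002.5,
        mmaxD=1005.0,
        replicate=1,
    )
    defaults.update(overrides)
    return PeptideUptakeRecord(**defaults)
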