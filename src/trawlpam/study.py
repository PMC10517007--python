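"""Published metadata of the trawl-depredation recording deposit.

These constants describe the dataset this package was built to process: a
single 192 kHz / 16-bit mono recording of bottlenose dolphins interacting
with a bottom trawl, of which 98 min 20 s were retained after trimming the
noise-only lead-in. They let worked examples and arithmetic checks run
without downloading the multi-gigabyte deposit itself.
"""

#: recorder sampling rate, Hz
SAMPLE_RATE = 192_000
#: recorder resolution, bits
BIT_DEPTH = 16
#: retained recording duration (98 min 20 s), seconds
RETAINED_SECONDS = 5900
#: analysis block length, seconds
BLOCK_SECONDS = 60
#: number of full 60-s analysis blocks
N_FULL_BLOCKS = 98
#: duration of the final partial block, seconds
LAST_BLOCK_SECONDS = 20
#: SNR threshold chosen at the sensitivity-curve plateau, dB
SELECTED_TH_DB = 10.0

#: deposited whistle segments and their quality-class sizes (1 = weak ... 3 = prominent)
WHISTLE_COUNT = 303
WHISTLE_CLASS_COUNTS = {1: 122, 2: 104, 3: 77}

#: overloaded-sample counts reported at 99% and 90% of the signal peak
OVERLOAD_COUNT_99 = 6_356_601
OVERLOAD_COUNT_90 = 15_689_091


def total_samples() -> int:
    """Sample count of the retained recording (duration x rate)."""
    return RETAINED_SECONDS * SAMPLE_RATE
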