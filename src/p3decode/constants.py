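"""Pipeline-wide default constants.

Every analysis constant used by more than one module lives here so that
configuration files and CLIs can override them in exactly one place.
"""

# --- preprocessing ---
BANDPASS_LOW_HZ = 0.3
BANDPASS_HIGH_HZ = 50.0
TARGET_RATE_HZ = 128
EPOCH_WINDOW_S = (0.0, 1.0)

# --- decoder architecture / training ---
N_TEMPORAL_FILTERS = 4          # F1
TEMPORAL_KERNEL_LEN = 64        # samples
DEPTH_MULTIPLIER = 2            # D (spatial filters per temporal filter)
SEPARABLE_KERNEL_LEN = 16
POOL1 = 4
POOL2 = 8
DROPOUT_P = 0.25
N_TRAIN_ITERATIONS = 100        # full passes over the training pool
BATCH_SIZE = 64

# --- sliding-window decoding ---
DECODE_SPAN_S = (-1.0, 1.0)     # epoch-start times relative to event onset
DECODE_STRIDE_SAMPLES = 4       # yields 65 outputs over [-1, +1] s at 128 Hz
N_DECODE_OUTPUTS = 65

# --- amplitude statistics ---
ROI_CHANNELS = ("Pz", "P1", "P2", "CP1", "CP2", "CPz")
AMPLITUDE_WINDOW_S = (0.400, 0.850)
N_POWER_REPETITIONS = 100
RT_PERCENTILE_CUTS = (33.0, 66.0)
FIXATION_SPLIT_THRESHOLD_S = 0.2194

# --- synthetic-data defaults ---
TTI_TAU_S = 2.5                 # saturating amplitude rule time constant
RT_RESIDUAL_MU = -1.2           # lognormal RT residual (seconds)
RT_RESIDUAL_SIGMA = 0.5
NOISE_PINK_EXPONENT = 1.0
NOISE_OSC_FREQ_HZ = 10.0
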