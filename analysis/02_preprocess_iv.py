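#!/usr/bin/env python
"""Reduce raw sweeps to normalized I-V curves with QC.

Reads the sweep CSVs from step 01 and applies the reduction rules:
background subtraction (Ca²⁺-free sweeps), rundown correction by the
+80 mV pre-pulse fraction, normalization to the +120 mV response, and the
<2 mV voltage-offset acceptance filter. Writes tidy aggregated I-V tables
(mean ± s.e.m. across accepted patches) and per-patch QC logs.
"""

import logging

from patchperm.pipeline import RunConfig, run_pipeline

logging.basicConfig(level=logging.INFO, format="%(message)s")

config = RunConfig(seed=7)
run_pipeline(config, stage="preprocess")
print(f"aggregated I-V tables and QC reports written to {config.outdir}/")
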