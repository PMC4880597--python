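# Mouse corpus callosum measurements

The electron-microscopy axon diameter measurements (>20,000 manually
measured axons across genu, body and splenium) are distributed separately
and are not bundled here.

To run the measured-data reproduction (`tests/test_acceptance.py::
test_measured_mouse_corpus_callosum_reproduction` and the `stats` / `rank`
CLI examples in the top-level README):

1. Obtain the measurement tables from the public AxonDiameter repository
   (github.com/sepehrband/AxonDiameter).
2. Export them as a single CSV named `measurements.csv` in this directory
   with columns:

   ```
   diameter_um,region,specimen
   0.42,genu,mouse1
   ...
   ```

   Diameters are in micrometres; `region` is one of genu/body/splenium.
   For raw one-diameter-per-line dumps use the reader's headerless dialect
   (`axondist.read_measurements(path, headerless=True)`) and add labels
   yourself.

Without this file the reproduction test fails with a clear message; all
other tests and the acceptance script are self-contained.
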