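import os

os.environ.setdefault("MPLBACKEND", "Agg")
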