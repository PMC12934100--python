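{
  "up": ["TACSTD2", "EREG", "SOX9", "LPPR4"],
  "down": ["LAMA1", "TMEM27", "AMIGO2", "MGAT5B"]
}
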