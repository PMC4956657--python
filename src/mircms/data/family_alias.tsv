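# mature-id or base family -> reported family (curated merges)
miR156	miR156/157
miR157	miR156/157
miR165	miR165/166
miR166	miR165/166
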