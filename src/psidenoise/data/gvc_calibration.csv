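delta,k_max
0.28586617606613873,26.0
0.4051047428230269,43.0
0.4985308344499811,61.0
0.5715304191719417,81.0
0.6378909019446468,104.0
0.6915093727693762,131.0
0.701406671540832,133.0
0.7493549761816419,167.0
0.7552764326527892,168.0
0.8054696780728294,217.0
0.8083842281254879,223.0
0.8564067428352411,304.0
0.8607875763903777,311.0
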