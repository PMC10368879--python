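attributed to	attributed to
secondary to	secondary to
due to	due to
induced	induced
caused by	caused by
related to	related to
associated with	associated with
consistent with	consistent with
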