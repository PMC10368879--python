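atezolizumab	atezolizumab|tecentriq
ipilimumab	ipilimumab|yervoy
nivolumab	nivolumab|opdivo
pembrolizumab	pembrolizumab|keytruda
tremelimumab	tremelimumab|imjudo
avelumab	avelumab|bavencio
durvalumab	durvalumab|imfinzi
cemiplimab	cemiplimab|libtayo
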