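samantha
sarah
simon
steve
susan
sally
sean
sophie
stanley
stella
stuart
sheila
sidney
sandra
scott
serena
seth
shane
sharon
shirley
sylvia
spencer
saul
solomon
sebastian
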