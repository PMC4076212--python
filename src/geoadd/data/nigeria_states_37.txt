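37
Abia 7 Akwa_Ibom Anambra Cross_River Ebonyi Enugu Imo Rivers
Abuja 4 Kaduna Kogi Nassarawa Niger
Adamawa 3 Borno Gombe Taraba
Akwa_Ibom 3 Abia Cross_River Rivers
Anambra 5 Abia Delta Enugu Imo Kogi
Bauchi 7 Gombe Jigawa Kaduna Kano Plateau Taraba Yobe
Bayelsa 2 Delta Rivers
Benue 6 Cross_River Ebonyi Enugu Kogi Nassarawa Taraba
Borno 3 Adamawa Gombe Yobe
Cross_River 4 Abia Akwa_Ibom Benue Ebonyi
Delta 5 Anambra Bayelsa Edo Ondo Rivers
Ebonyi 4 Abia Benue Cross_River Enugu
Edo 4 Delta Ekiti Kogi Ondo
Ekiti 5 Edo Kogi Kwara Ondo Osun
Enugu 5 Abia Anambra Benue Ebonyi Kogi
Gombe 5 Adamawa Bauchi Borno Taraba Yobe
Imo 3 Abia Anambra Rivers
Jigawa 4 Bauchi Kano Katsina Yobe
Kaduna 8 Abuja Bauchi Kano Katsina Nassarawa Niger Plateau Zamfara
Kano 4 Bauchi Jigawa Kaduna Katsina
Katsina 4 Jigawa Kaduna Kano Zamfara
Kebbi 3 Niger Sokoto Zamfara
Kogi 10 Abuja Anambra Benue Edo Ekiti Enugu Kwara Nassarawa Niger Ondo
Kwara 5 Ekiti Kogi Niger Osun Oyo
Lagos 1 Ogun
Nassarawa 6 Abuja Benue Kaduna Kogi Plateau Taraba
Niger 6 Abuja Kaduna Kebbi Kogi Kwara Zamfara
Ogun 4 Lagos Ondo Osun Oyo
Ondo 6 Delta Edo Ekiti Kogi Ogun Osun
Osun 5 Ekiti Kwara Ogun Ondo Oyo
Oyo 3 Kwara Ogun Osun
Plateau 4 Bauchi Kaduna Nassarawa Taraba
Rivers 5 Abia Akwa_Ibom Bayelsa Delta Imo
Sokoto 2 Kebbi Zamfara
Taraba 6 Adamawa Bauchi Benue Gombe Nassarawa Plateau
Yobe 4 Bauchi Borno Gombe Jigawa
Zamfara 5 Kaduna Katsina Kebbi Niger Sokoto
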